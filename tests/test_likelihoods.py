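"""Closed-form examples and structural properties of the likelihood components."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, kstest, norm, poisson

from gensmr.likelihoods import (
    camera_total_rate,
    half_normal_rate,
    joint_log_density,
    loglik_marking,
    loglik_resight_identified,
    loglik_telemetry,
    loglik_unid_marked,
    loglik_unmarked,
    marking_detection_prob,
)
from gensmr.model import (
    CAMERA,
    MARKING_TRAP,
    AugmentedState,
    DetectorArray,
    ModelConfig,
    Parameters,
    SMRDataset,
    StateSpace,
)

from conftest import make_tiny_dataset, make_tiny_state


class TestHalfNormalRate:
    @pytest.mark.parametrize(
        "d, lam0, sigma, expected",
        [
            (0.0, 0.5, 0.05, 0.5),
            (1.7, 0.0, 0.3, 0.0),
            (0.05, 0.5, 0.05, 0.5 * np.exp(-0.5)),
        ],
    )
    def test_closed_form(self, d, lam0, sigma, expected):
        assert half_normal_rate(d, lam0, sigma) == pytest.approx(expected, abs=1e-12)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            half_normal_rate(0.1, 0.5, 0.0)
        with pytest.raises(ValueError):
            half_normal_rate(0.1, 0.5, -1.0)

    @settings(deadline=None, max_examples=50)
    @given(
        d=st.lists(st.floats(0, 10), min_size=2, max_size=10),
        lam0=st.floats(0.01, 2.0),
        sigma=st.floats(0.01, 5.0),
    )
    def test_monotone_nonincreasing_in_distance(self, d, lam0, sigma):
        dd = np.sort(np.asarray(d))
        rates = half_normal_rate(dd, lam0, sigma)
        assert np.all(np.diff(rates) <= 1e-15)


class TestMarkingDetectionProb:
    def test_at_zero_distance_equals_baseline(self):
        assert marking_detection_prob(0.0, 0.35, 0.05) == pytest.approx(0.35)

    def test_vanishes_at_large_distance(self):
        assert marking_detection_prob(1e3, 0.35, 0.05) == pytest.approx(0.0, abs=1e-300)

    def test_at_one_sigma(self):
        assert marking_detection_prob(0.05, 0.35, 0.05) == pytest.approx(
            0.35 * np.exp(-0.5), rel=1e-12
        )

    def test_cloglog_form(self):
        lam = 0.35 * np.exp(-0.5)
        assert marking_detection_prob(0.05, 0.35, 0.05, "cloglog") == pytest.approx(
            1.0 - np.exp(-lam), rel=1e-12
        )
        # hazard form always yields a valid probability even for rates > 1
        assert 0 < marking_detection_prob(0.0, 3.0, 1.0, "cloglog") < 1


class TestCameraTotalRate:
    def test_empty_center_set(self):
        assert camera_total_rate(np.empty((0, 2)), (0.5, 0.5), 0.5, 0.05) == 0.0

    def test_single_center_on_camera(self):
        assert camera_total_rate([(0.5, 0.5)], (0.5, 0.5), 0.5, 0.05) == pytest.approx(0.5)

    def test_two_centers_closed_form(self):
        val = camera_total_rate([(0.5, 0.5), (0.55, 0.5)], (0.5, 0.5), 0.5, 0.05)
        assert val == pytest.approx(0.5 * (1 + np.exp(-0.5)), rel=1e-12)

    def test_occasion_aggregation_multiplies(self):
        one = camera_total_rate([(0.4, 0.4)], (0.5, 0.5), 0.5, 0.1, n_occasions=1)
        four = camera_total_rate([(0.4, 0.4)], (0.5, 0.5), 0.5, 0.1, n_occasions=4)
        assert four == pytest.approx(4 * one)


def _single_individual_instance(w_value: float):
    """One marked animal sitting exactly on the only trap, one occasion."""
    space = StateSpace(0, 1, 0, 1)
    traps = DetectorArray(np.array([[0.5, 0.5]]), MARKING_TRAP, np.ones((1, 1)))
    cameras = DetectorArray(np.array([[0.5, 0.5]]), CAMERA, np.zeros((1, 1)))
    ds = SMRDataset(
        traps=traps,
        cameras=cameras,
        marking=np.full((1, 1, 1), w_value),
        resight_identified=np.zeros((1, 1, 1)),
        unid_marked_counts=np.zeros((1, 1)),
        unmarked_counts=np.zeros((1, 1)),
        telemetry=[np.empty((0, 2))],
        alive=np.ones((1, 1)),
        state_space=space,
    )
    state = AugmentedState(
        z=np.array([1, 0]),
        s=np.array([[0.5, 0.5], [0.1, 0.1]]),
        params=Parameters(0.35, 0.5, 0.05, 1.0, 0.5),
        M=2,
        m=1,
    )
    return ds, state


class TestLoglikMarking:
    def test_capture_at_own_trap(self):
        ds, state = _single_individual_instance(1.0)
        assert loglik_marking(ds, state) == pytest.approx(np.log(0.35))

    def test_no_capture_at_own_trap(self):
        ds, state = _single_individual_instance(0.0)
        assert loglik_marking(ds, state) == pytest.approx(np.log(0.65))

    def test_excluded_augmented_contribute_nothing(self, tiny_dataset, tiny_state):
        st0 = tiny_state.copy()
        st0.z[tiny_dataset.m :] = 0
        base = loglik_marking(tiny_dataset, st0)
        st0.s[tiny_dataset.m :] = [0.35, 0.3]  # right next to a trap, but z=0
        assert loglik_marking(tiny_dataset, st0) == pytest.approx(base)

    def test_impossible_capture_gives_neg_inf(self):
        ds, state = _single_individual_instance(1.0)
        state.params.lam0_mark = 0.0
        assert loglik_marking(ds, state) == -np.inf


class TestLoglikResightIdentified:
    @pytest.mark.parametrize(
        "y, delta, lam, expected",
        [
            (0.0, 1.0, 0.5, -0.5),
            (1.0, 0.5, 0.5, np.log(0.25) - 0.25),
        ],
    )
    def test_single_cell_poisson(self, y, delta, lam, expected):
        space = StateSpace(0, 1, 0, 1)
        traps = DetectorArray(np.array([[0.2, 0.2]]), MARKING_TRAP, np.zeros((1, 1)))
        cameras = DetectorArray(np.array([[0.5, 0.5]]), CAMERA, np.ones((1, 1)))
        ds = SMRDataset(
            traps=traps,
            cameras=cameras,
            marking=np.zeros((1, 1, 1)),
            resight_identified=np.full((1, 1, 1), y),
            unid_marked_counts=np.zeros((1, 1)),
            unmarked_counts=np.zeros((1, 1)),
            telemetry=[np.empty((0, 2))],
            alive=np.ones((1, 1)),
            state_space=space,
        )
        state = AugmentedState(
            z=np.array([1]),
            s=np.array([[0.5, 0.5]]),  # on the camera: rate = lam0_resight
            params=Parameters(0.3, lam, 0.05, delta, 0.5),
            M=1,
            m=1,
        )
        assert loglik_resight_identified(ds, state) == pytest.approx(expected)

    def test_zero_delta_with_no_identifications_is_exact_zero(self, tiny_dataset, tiny_state):
        st0 = tiny_state.copy()
        st0.params.delta = 0.0
        ds = make_tiny_dataset()
        ds.resight_identified[:] = 0.0
        assert loglik_resight_identified(ds, st0) == 0.0

    def test_identification_with_zero_delta_impossible(self, tiny_dataset, tiny_state):
        st0 = tiny_state.copy()
        st0.params.delta = 0.0
        assert loglik_resight_identified(tiny_dataset, st0) == -np.inf


class TestLoglikUnidMarked:
    def test_full_identification_all_zero(self, tiny_dataset, tiny_state):
        ds = make_tiny_dataset()
        ds.unid_marked_counts[:] = 0.0
        st1 = tiny_state.copy()
        st1.params.delta = 1.0
        assert loglik_unid_marked(ds, st1) == 0.0

    def test_unidentified_count_with_full_identification_impossible(
        self, tiny_dataset, tiny_state
    ):
        st1 = tiny_state.copy()
        st1.params.delta = 1.0
        assert loglik_unid_marked(tiny_dataset, st1) == -np.inf

    def test_single_animal_at_camera(self):
        space = StateSpace(0, 1, 0, 1)
        traps = DetectorArray(np.array([[0.2, 0.2]]), MARKING_TRAP, np.zeros((1, 1)))
        cameras = DetectorArray(np.array([[0.5, 0.5]]), CAMERA, np.ones((1, 1)))
        ds = SMRDataset(
            traps=traps,
            cameras=cameras,
            marking=np.zeros((1, 1, 1)),
            resight_identified=np.zeros((1, 1, 1)),
            unid_marked_counts=np.zeros((1, 1)),
            unmarked_counts=np.zeros((1, 1)),
            telemetry=[np.empty((0, 2))],
            alive=np.ones((1, 1)),
            state_space=space,
        )
        state = AugmentedState(
            z=np.array([1]),
            s=np.array([[0.5, 0.5]]),
            params=Parameters(0.3, 0.5, 0.05, 0.5, 0.5),
            M=1,
            m=1,
        )
        # mean = (1-0.5)*0.5 = 0.25, observation 0 -> logpmf = -0.25
        assert loglik_unid_marked(ds, state) == pytest.approx(-0.25)

    def test_count_from_dead_individual_impossible(self):
        space = StateSpace(0, 1, 0, 1)
        traps = DetectorArray(np.array([[0.2, 0.2]]), MARKING_TRAP, np.zeros((1, 1)))
        cameras = DetectorArray(np.array([[0.5, 0.5]]), CAMERA, np.ones((1, 1)))
        ds = SMRDataset(
            traps=traps,
            cameras=cameras,
            marking=np.zeros((1, 1, 1)),
            resight_identified=np.zeros((1, 1, 1)),
            unid_marked_counts=np.ones((1, 1)),
            unmarked_counts=np.zeros((1, 1)),
            telemetry=[np.empty((0, 2))],
            alive=np.zeros((1, 1)),
            state_space=space,
        )
        state = AugmentedState(
            z=np.array([1]),
            s=np.array([[0.5, 0.5]]),
            params=Parameters(0.3, 0.5, 0.05, 0.5, 0.5),
            M=1,
            m=1,
        )
        assert loglik_unid_marked(ds, state) == -np.inf


class TestLoglikUnmarked:
    def test_no_included_augmented_and_no_counts(self, tiny_dataset, tiny_state):
        ds = make_tiny_dataset()
        ds.unmarked_counts[:] = 0.0
        st0 = tiny_state.copy()
        st0.z[tiny_dataset.m :] = 0
        assert loglik_unmarked(ds, st0) == 0.0

    def test_counts_without_included_augmented_impossible(self, tiny_dataset, tiny_state):
        st0 = tiny_state.copy()
        st0.z[tiny_dataset.m :] = 0
        assert loglik_unmarked(tiny_dataset, st0) == -np.inf

    def test_aggregated_poisson_closed_form(self):
        space = StateSpace(0, 1, 0, 1)
        traps = DetectorArray(np.array([[0.2, 0.2]]), MARKING_TRAP, np.zeros((1, 1)))
        cameras = DetectorArray(np.array([[0.5, 0.5]]), CAMERA, np.ones((1, 4)))
        counts = np.zeros((1, 4))
        counts[0, 0] = 2.0
        ds = SMRDataset(
            traps=traps,
            cameras=cameras,
            marking=np.zeros((0, 1, 1)),
            resight_identified=np.zeros((0, 1, 4)),
            unid_marked_counts=np.zeros((1, 4)),
            unmarked_counts=counts,
            telemetry=[],
            alive=np.zeros((0, 4)),
            state_space=space,
        )
        state = AugmentedState(
            z=np.array([1]),
            s=np.array([[0.5, 0.5]]),
            params=Parameters(0.3, 0.5, 0.05, 0.5, 0.5),
            M=1,
            m=0,
        )
        # occasion-wise: Poisson(2; 0.5) at k=0 and Poisson(0; 0.5) x3;
        # totals match Poisson(2; 2.0) up to the multinomial constant
        expected = poisson.logpmf(2, 0.5) + 3 * poisson.logpmf(0, 0.5)
        assert loglik_unmarked(ds, state) == pytest.approx(expected)
        # occasion-wise likelihood = aggregated likelihood + log multinomial pmf
        from scipy.stats import multinomial

        assert loglik_unmarked(ds, state) == pytest.approx(
            poisson.logpmf(2, 2.0) + multinomial.logpmf([2, 0, 0, 0], 2, [0.25] * 4)
        )


class TestLoglikTelemetry:
    def test_single_fix_at_center(self):
        ds = make_tiny_dataset()
        ds.telemetry = [np.array([[0.3, 0.4]]), np.empty((0, 2))]
        state = make_tiny_state(ds)
        state.s[0] = [0.3, 0.4]
        state.params.sigma = 1.0
        assert loglik_telemetry(ds, state) == pytest.approx(2 * norm.logpdf(0, 0, 1))

    def test_translation_invariance(self, tiny_dataset, tiny_state):
        base = loglik_telemetry(tiny_dataset, tiny_state)
        shifted = make_tiny_dataset()
        shifted.telemetry = [t + np.array([0.05, -0.03]) for t in shifted.telemetry]
        st2 = tiny_state.copy()
        st2.s[: shifted.m] += np.array([0.05, -0.03])
        assert loglik_telemetry(shifted, st2) == pytest.approx(base, rel=1e-12)

    def test_doubling_sigma_at_mean_costs_2_log_2(self):
        ds = make_tiny_dataset()
        ds.telemetry = [np.array([[0.3, 0.4]]), np.empty((0, 2))]
        state = make_tiny_state(ds)
        state.s[0] = [0.3, 0.4]
        state.params.sigma = 1.0
        ll1 = loglik_telemetry(ds, state)
        state.params.sigma = 2.0
        ll2 = loglik_telemetry(ds, state)
        assert ll1 - ll2 == pytest.approx(2 * np.log(2))


class TestJointLogDensity:
    def test_sum_of_components(self, tiny_dataset, tiny_state):
        cfg = ModelConfig()
        total = joint_log_density(tiny_dataset, tiny_state, cfg)
        comp_sum = (
            loglik_marking(tiny_dataset, tiny_state, cfg)
            + loglik_resight_identified(tiny_dataset, tiny_state)
            + loglik_unid_marked(tiny_dataset, tiny_state)
            + loglik_unmarked(tiny_dataset, tiny_state)
            + loglik_telemetry(tiny_dataset, tiny_state)
        )
        p = tiny_state.params
        space = tiny_dataset.state_space
        priors = (
            -np.log(cfg.lam0_resight_max)
            - np.log(cfg.sigma_upper(space))
            - tiny_state.M * np.log(space.area)
            + tiny_state.z.sum() * np.log(p.psi)
            + (tiny_state.M - tiny_state.z.sum()) * np.log(1 - p.psi)
        )
        assert total == pytest.approx(comp_sum + priors, rel=1e-12)

    def test_parameter_outside_prior_support(self, tiny_dataset, tiny_state):
        bad = tiny_state.copy()
        bad.params.lam0_resight = 2.5
        assert joint_log_density(tiny_dataset, bad) == -np.inf
        bad = tiny_state.copy()
        bad.s[3] = [1.5, 0.5]
        assert joint_log_density(tiny_dataset, bad) == -np.inf

    def test_prior_only_with_empty_data(self):
        space = StateSpace(0, 1, 0, 1)
        traps = DetectorArray(np.array([[0.4, 0.4]]), MARKING_TRAP, np.zeros((1, 1)))
        cameras = DetectorArray(np.array([[0.6, 0.6]]), CAMERA, np.zeros((1, 1)))
        ds = SMRDataset(
            traps=traps,
            cameras=cameras,
            marking=np.zeros((0, 1, 1)),
            resight_identified=np.zeros((0, 1, 1)),
            unid_marked_counts=np.zeros((1, 1)),
            unmarked_counts=np.zeros((1, 1)),
            telemetry=[],
            alive=np.zeros((0, 1)),
            state_space=space,
        )
        state = AugmentedState(
            z=np.array([1, 0]),
            s=np.array([[0.5, 0.5], [0.2, 0.2]]),
            params=Parameters(0.3, 0.5, 0.2, 0.4, 0.45),
            M=2,
            m=0,
        )
        cfg = ModelConfig()
        expected = (
            -np.log(2.0)
            - np.log(0.5)
            + np.log(0.45)
            + np.log(0.55)
        )
        assert joint_log_density(ds, state, cfg) == pytest.approx(expected)

    def test_finite_for_interior_parameters(self, tiny_dataset, tiny_state):
        assert np.isfinite(joint_log_density(tiny_dataset, tiny_state))


class TestThinningConsistency:
    """Poisson thinning: splitting a Poisson count binomially is the same
    joint law as two independent Poissons with the split means."""

    @pytest.mark.parametrize("lam", [0.1, 0.5, 2.0])
    @pytest.mark.parametrize("delta", [0.2, 0.5, 0.9])
    def test_pointwise_identity(self, lam, delta):
        for y in range(11):
            for ym in range(y + 1):
                lhs = poisson.pmf(ym, delta * lam) * poisson.pmf(y - ym, (1 - delta) * lam)
                rhs = poisson.pmf(y, lam) * binom.pmf(ym, y, delta)
                assert lhs == pytest.approx(rhs, rel=1e-10)

    @pytest.mark.parametrize("lam", [0.1, 0.5, 2.0])
    def test_marginal_sum(self, lam):
        delta = 0.37
        for y in range(11):
            total = sum(
                poisson.pmf(ym, delta * lam) * poisson.pmf(y - ym, (1 - delta) * lam)
                for ym in range(y + 1)
            )
            assert total == pytest.approx(poisson.pmf(y, lam), rel=1e-10)


class TestAggregation:
    def test_total_count_distribution_identical(self, rng):
        lam, K = 0.7, 4
        occasionwise = rng.poisson(lam, size=(20000, K)).sum(axis=1)
        aggregated = rng.poisson(lam * K, size=20000)
        stat = kstest(occasionwise, aggregated).pvalue
        assert stat > 0.01


class TestSCRReduction:
    """With delta = 1 and the whole population marked, the joint reduces to
    a standard spatial capture-recapture Poisson count model."""

    def test_against_brute_force_scr(self, rng):
        space = StateSpace(0, 1, 0, 1)
        traps = DetectorArray(np.array([[0.35, 0.5]]), MARKING_TRAP, np.ones((1, 2)))
        cameras = DetectorArray(
            np.array([[0.3, 0.3], [0.7, 0.3], [0.3, 0.7], [0.7, 0.7]]),
            CAMERA,
            np.ones((4, 3)),
        )
        m, M = 2, 2
        marking = rng.integers(0, 2, size=(m, 1, 2)).astype(float)
        y = rng.poisson(0.8, size=(m, 4, 3)).astype(float)
        telemetry = [rng.normal(0.5, 0.1, size=(5, 2)) for _ in range(m)]
        ds = SMRDataset(
            traps=traps,
            cameras=cameras,
            marking=marking,
            resight_identified=y,
            unid_marked_counts=np.zeros((4, 3)),
            unmarked_counts=np.zeros((4, 3)),
            telemetry=telemetry,
            alive=np.ones((m, 3)),
            state_space=space,
        )
        ds.validate()
        params = Parameters(0.25, 0.6, 0.18, 1.0, 0.5)
        state = AugmentedState(
            z=np.ones(M, dtype=int),
            s=np.array([[0.4, 0.45], [0.6, 0.55]]),
            params=params,
            M=M,
            m=m,
        )
        model_ll = (
            loglik_marking(ds, state)
            + loglik_resight_identified(ds, state)
            + loglik_unid_marked(ds, state)
            + loglik_unmarked(ds, state)
            + loglik_telemetry(ds, state)
        )
        # brute-force SCR: Bernoulli marking + Poisson counts + normal fixes
        brute = 0.0
        for i in range(m):
            for j in range(1):
                d = np.linalg.norm(state.s[i] - traps.coords[j])
                p = params.lam0_mark * np.exp(-(d**2) / (2 * params.sigma**2))
                for k in range(2):
                    brute += np.log(p) if marking[i, j, k] else np.log(1 - p)
            for j in range(4):
                d = np.linalg.norm(state.s[i] - cameras.coords[j])
                lam = params.lam0_resight * np.exp(-(d**2) / (2 * params.sigma**2))
                for k in range(3):
                    brute += poisson.logpmf(y[i, j, k], lam)
            for fix in telemetry[i]:
                brute += norm.logpdf(fix, state.s[i], params.sigma).sum()
        assert model_ll == pytest.approx(brute, rel=1e-10)
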