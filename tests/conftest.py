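"""Shared fixtures: small hand-built datasets and helpers."""

import numpy as np
import pytest

from gensmr.model import (
    CAMERA,
    MARKING_TRAP,
    AugmentedState,
    DetectorArray,
    Parameters,
    SMRDataset,
    StateSpace,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_tiny_dataset(seed: int = 5) -> SMRDataset:
    """Small hand-built dataset exercising every data stream.

    2 marked individuals, 2 traps x 2 occasions, 4 cameras x 3 occasions
    with one zero-effort cell, one dead individual-occasion, telemetry on
    both individuals.
    """
    r = np.random.default_rng(seed)
    space = StateSpace(0.0, 1.0, 0.0, 1.0)
    traps = DetectorArray(
        np.array([[0.3, 0.3], [0.7, 0.3]]), MARKING_TRAP, np.ones((2, 2))
    )
    eff_c = np.ones((4, 3))
    eff_c[3, 2] = 0.0
    cameras = DetectorArray(
        np.array([[0.3, 0.7], [0.7, 0.7], [0.5, 0.5], [0.2, 0.2]]), CAMERA, eff_c
    )
    marking = np.zeros((2, 2, 2))
    marking[0, 0, 0] = 1
    marking[1, 1, 1] = 1
    alive = np.ones((2, 3))
    alive[1, 2] = 0.0  # individual 1 dead on the last resight occasion
    resight = np.zeros((2, 4, 3))
    resight[0, 0, 0] = 2
    resight[0, 2, 1] = 1
    resight[1, 1, 0] = 1
    nnid = np.zeros((4, 3))
    nnid[0, 1] = 1
    nnid[2, 0] = 2
    nun = np.zeros((4, 3))
    nun[1, 1] = 3
    nun[2, 2] = 1
    nun[0, 0] = 2
    telemetry = [
        np.array([0.32, 0.55]) + 0.1 * r.standard_normal((6, 2)),
        np.array([0.66, 0.5]) + 0.1 * r.standard_normal((4, 2)),
    ]
    ds = SMRDataset(
        traps=traps,
        cameras=cameras,
        marking=marking,
        resight_identified=resight,
        unid_marked_counts=nnid,
        unmarked_counts=nun,
        telemetry=telemetry,
        alive=alive,
        state_space=space,
    )
    ds.validate()
    return ds


def make_tiny_state(dataset: SMRDataset, M: int = 6, seed: int = 9) -> AugmentedState:
    r = np.random.default_rng(seed)
    s = dataset.state_space.sample_uniform(M, r)
    s[0] = [0.33, 0.52]
    s[1] = [0.64, 0.48]
    z = np.array([1, 1, 1, 0, 1, 0])
    params = Parameters(
        lam0_mark=0.3, lam0_resight=0.5, sigma=0.2, delta=0.4, psi=0.45
    )
    return AugmentedState(z=z, s=s, params=params, M=M, m=dataset.m)


@pytest.fixture
def tiny_dataset():
    return make_tiny_dataset()


@pytest.fixture
def tiny_state(tiny_dataset):
    return make_tiny_state(tiny_dataset)


def make_totals_dataset(n_identified: int, n_unidentified: int, seed: int = 3):
    """Dataset whose identified / unidentified-marked event totals are fixed.

    Synthetic stand-in for a field study's printed resighting totals: the
    counts are spread over 2 marked individuals and 4 cameras; telemetry
    keeps sigma identifiable.
    """
    r = np.random.default_rng(seed)
    space = StateSpace(0.0, 1.0, 0.0, 1.0)
    traps = DetectorArray(
        np.array([[0.4, 0.4], [0.6, 0.6]]), MARKING_TRAP, np.ones((2, 2))
    )
    cameras = DetectorArray(
        np.array([[0.35, 0.6], [0.65, 0.6], [0.4, 0.35], [0.6, 0.35]]),
        CAMERA,
        np.ones((4, 4)),
    )
    marking = np.zeros((2, 2, 2))
    marking[0, 0, 0] = 1
    marking[1, 1, 0] = 1
    resight = np.zeros((2, 4, 4))
    flat = r.multinomial(n_identified, np.ones(32) / 32)
    resight += flat.reshape(2, 4, 4)
    nnid = r.multinomial(n_unidentified, np.ones(16) / 16).reshape(4, 4).astype(float)
    nun = r.poisson(1.0, size=(4, 4)).astype(float)
    telemetry = [
        np.array([0.4, 0.5]) + 0.12 * r.standard_normal((40, 2)),
        np.array([0.6, 0.5]) + 0.12 * r.standard_normal((40, 2)),
    ]
    ds = SMRDataset(
        traps=traps,
        cameras=cameras,
        marking=marking,
        resight_identified=resight,
        unid_marked_counts=nnid,
        unmarked_counts=nun,
        telemetry=telemetry,
        alive=np.ones((2, 4)),
        state_space=space,
    )
    ds.validate()
    assert ds.n_identified_events == n_identified
    assert ds.n_unidentified_marked_events == n_unidentified
    return ds
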