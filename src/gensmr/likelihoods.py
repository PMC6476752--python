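"""Likelihood components of the joint posterior density.

These are straightforward vectorized numpy/scipy implementations, used as
the reference implementation throughout the test suite; the MCMC kernels in
:mod:`gensmr._kernels` implement the same quantities with incremental
updates and are checked against these functions.

Notation: distances d_ij between activity center s_i and detector x_j enter
through the half-normal kernel exp(-d_ij^2 / (2 sigma^2)). The resighting
encounter rate is lam0_resight times that kernel; the per-occasion marking
capture probability is lam0_mark times that kernel (or its complementary
log-log transform when ``marking_model="cloglog"``).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, xlogy, xlog1py

from .model import AugmentedState, ModelConfig, SMRDataset

__all__ = [
    "half_normal_rate",
    "marking_detection_prob",
    "camera_total_rate",
    "loglik_marking",
    "loglik_resight_identified",
    "loglik_unid_marked",
    "loglik_unmarked",
    "loglik_telemetry",
    "joint_log_density",
    "pairwise_sq_distances",
]


def pairwise_sq_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between rows of (n,2) ``a`` and (m,2) ``b``."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    diff = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def half_normal_rate(d, lam0, sigma):
    """Encounter rate lam0 * exp(-d^2 / (2 sigma^2)).

    Monotone nonincreasing in the distance ``d``; equals ``lam0`` at d=0.
    """
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    return lam0 * np.exp(-(d**2) / (2.0 * np.asarray(sigma, dtype=float) ** 2))


def marking_detection_prob(d, lam0_mark, sigma, model: str = "bernoulli"):
    """Per-occasion capture probability of the marking process.

    ``model="bernoulli"`` uses p = lam0_mark * exp(-d^2/(2 sigma^2)), which
    keeps lam0_mark interpretable as a probability coherent with its
    uniform-(0,1) prior. ``model="cloglog"`` uses the hazard form
    1 - exp(-lam0_mark * exp(-d^2/(2 sigma^2))).
    """
    lam = half_normal_rate(d, lam0_mark, sigma)
    if model == "bernoulli":
        if np.any(np.asarray(lam0_mark) > 1) or np.any(np.asarray(lam0_mark) < 0):
            raise ValueError("lam0_mark must lie in [0, 1] under the bernoulli model")
        return lam
    if model == "cloglog":
        return -np.expm1(-lam)
    raise ValueError(f"unknown marking model {model!r}")


def camera_total_rate(s_set, camera, lam0_resight, sigma, n_occasions: int = 1):
    """Total expected count Lambda_j at one camera.

    Sum of half-normal rates over the supplied activity centers, multiplied
    by the number of effort-on occasions. An empty center set gives 0.
    """
    s_set = np.asarray(s_set, dtype=float).reshape(-1, 2)
    if s_set.shape[0] == 0:
        return 0.0
    d2 = pairwise_sq_distances(s_set, np.asarray(camera, dtype=float).reshape(1, 2))
    return float(
        n_occasions * lam0_resight * np.exp(-d2 / (2.0 * sigma**2)).sum()
    )


def _kernel_matrix(s: np.ndarray, coords: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-pairwise_sq_distances(s, coords) / (2.0 * sigma**2))


def _poisson_logpmf(y, mu):
    # xlogy handles y=0, mu=0 -> 0 and y>0, mu=0 -> -inf
    with np.errstate(divide="ignore", invalid="ignore"):
        return xlogy(y, mu) - mu - gammaln(y + 1.0)


def loglik_marking(
    dataset: SMRDataset, state: AugmentedState, config: ModelConfig | None = None
) -> float:
    """Bernoulli log-likelihood of the marking capture histories.

    Individuals i <= m use their observed histories; augmented individuals
    with z_i = 1 contribute an all-zero history (they are real but were never
    captured, which is what makes them unmarked). z_i = 0 contributes nothing.
    """
    config = config or ModelConfig()
    p = marking_detection_prob(
        np.sqrt(pairwise_sq_distances(state.s, dataset.traps.coords)),
        state.params.lam0_mark,
        state.params.sigma,
        config.marking_model,
    )  # (M, Jm)
    eff = dataset.traps.effort  # (Jm, Km)
    m = dataset.m
    w = dataset.marking  # (m, Jm, Km)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_marked = eff[None, :, :] * (
            xlogy(w, p[:m, :, None]) + xlog1py(1.0 - w, -p[:m, :, None])
        )
    total = float(np.sum(ll_marked))
    # augmented, included individuals: all-zero histories
    z_aug = state.z[m:]
    if z_aug.any():
        with np.errstate(divide="ignore"):
            zero_ll = dataset.traps.occasions_on[None, :] * np.log1p(-p[m:])
        total += float(np.sum(z_aug[:, None] * zero_ll))
    if np.isnan(total):
        return -np.inf
    return total


def _marked_rates(dataset: SMRDataset, state: AugmentedState) -> np.ndarray:
    """(m, Jc) resighting rates lambda_ij for the marked individuals."""
    m = dataset.m
    return state.params.lam0_resight * _kernel_matrix(
        state.s[:m], dataset.cameras.coords, state.params.sigma
    )


def loglik_resight_identified(dataset: SMRDataset, state: AugmentedState, config=None) -> float:
    """Poisson log-likelihood of identified resights, mean delta * lambda_ij.

    Cells with zero effort or a dead individual are skipped (their mean is
    zero and the data are validated to be zero there).
    """
    lam = _marked_rates(dataset, state)  # (m, Jc)
    avail = dataset.cameras.effort[None, :, :] * dataset.alive[:, None, :]
    mu = state.params.delta * lam[:, :, None] * avail
    out = float(_poisson_logpmf(dataset.resight_identified, mu).sum())
    return -np.inf if np.isnan(out) else out


def loglik_unid_marked(dataset: SMRDataset, state: AugmentedState, config=None) -> float:
    """Poisson log-likelihood of marked-but-unidentified counts.

    Marginalizing the latent per-individual histories over the binomial
    identification thinning leaves nnid_jk ~ Poisson((1-delta) *
    sum_{i<=m, alive} lambda_ij) on effort-on cells.
    """
    lam = _marked_rates(dataset, state)  # (m, Jc)
    # sum over marked individuals alive on occasion k
    sa = np.einsum("ij,ik->jk", lam, dataset.alive)  # (Jc, Kres)
    mu = (1.0 - state.params.delta) * sa * dataset.cameras.effort
    out = float(_poisson_logpmf(dataset.unid_marked_counts, mu).sum())
    return -np.inf if np.isnan(out) else out


def loglik_unmarked(dataset: SMRDataset, state: AugmentedState, config=None) -> float:
    """Poisson log-likelihood of unmarked counts.

    The mean at camera j sums the rates of augmented individuals with
    z_i = 1 only: marked animals' detections are accounted for by the other
    two streams.
    """
    m = dataset.m
    z_aug = state.z[m:].astype(float)
    if z_aug.sum() == 0:
        g = np.zeros(dataset.cameras.J)
    else:
        ker = _kernel_matrix(state.s[m:], dataset.cameras.coords, state.params.sigma)
        g = z_aug @ ker
    mu = state.params.lam0_resight * g[:, None] * dataset.cameras.effort
    out = float(_poisson_logpmf(dataset.unmarked_counts, mu).sum())
    return -np.inf if np.isnan(out) else out


def loglik_telemetry(dataset: SMRDataset, state: AugmentedState, config=None) -> float:
    """Bivariate-normal log-density of the GPS fixes around each center.

    Independent x/y coordinates, common standard deviation sigma; only
    marked individuals with at least one fix contribute.
    """
    sigma = state.params.sigma
    total = 0.0
    for i, fixes in enumerate(dataset.telemetry):
        if fixes.shape[0] == 0:
            continue
        n = fixes.shape[0]
        dev = np.sum((fixes - state.s[i]) ** 2)
        total += -n * np.log(2.0 * np.pi * sigma**2) - dev / (2.0 * sigma**2)
    return float(total)


def joint_log_density(
    dataset: SMRDataset, state: AugmentedState, config: ModelConfig | None = None
) -> float:
    """Full joint log density: five likelihood components plus priors.

    Uniform priors contribute constants inside their support and -inf
    outside; the inclusion indicators of the augmented individuals
    contribute Bernoulli(psi) terms; every activity center carries a
    uniform prior over the state space.
    """
    config = config or ModelConfig()
    space = dataset.state_space
    if space is None:
        raise ValueError("dataset has no state space")
    p = state.params
    sig_hi = config.sigma_upper(space)
    if not (0.0 < p.lam0_mark < config.lam0_mark_max):
        return -np.inf
    if not (0.0 < p.lam0_resight < config.lam0_resight_max):
        return -np.inf
    if not (0.0 < p.sigma < sig_hi):
        return -np.inf
    if not (0.0 <= p.delta <= 1.0 and 0.0 < p.psi < 1.0):
        return -np.inf
    if not space.contains(state.s).all():
        return -np.inf

    lp = (
        -np.log(config.lam0_mark_max)
        - np.log(config.lam0_resight_max)
        - np.log(sig_hi)
        - state.M * np.log(space.area)
    )
    # every slot of the augmented superpopulation carries z_i ~ Bernoulli(psi);
    # for the marked individuals z_i = 1 is observed, so they contribute too
    lp += float(xlogy(state.z, p.psi).sum() + xlog1py(1 - state.z, -p.psi).sum())

    for component in (
        loglik_marking,
        loglik_resight_identified,
        loglik_unid_marked,
        loglik_unmarked,
        loglik_telemetry,
    ):
        val = component(dataset, state, config)
        if not np.isfinite(val):
            return -np.inf
        lp += val
    return float(lp)
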