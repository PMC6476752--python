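"""Metropolis-within-Gibbs sampler for the augmented posterior.

The sampler operates on the data-augmented parameter vector
(lam0_mark, lam0_resight, sigma, delta, psi, z_1..M, s_1..M): conjugate
Gibbs draws for psi and delta, Gibbs for the inclusion indicators, and
adaptive random-walk Metropolis for everything else. The default likelihood
marginalizes the latent unidentified histories analytically; an
independently-coded latent-imputation sampler (:func:`run_mcmc_latent`)
serves as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .model import AugmentedState, ModelConfig, Parameters, SMRDataset

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "init_state",
    "run_mcmc",
    "run_mcmc_latent",
    "delta_posterior",
    "prepare_arrays",
    "update_activity_center",
    "update_z",
    "update_psi",
    "update_delta",
    "update_rate_params",
]

PARAM_NAMES = ("lam0_mark", "lam0_resight", "sigma", "delta", "psi", "N", "D")


@dataclass
class MCMCConfig(ModelConfig):
    """MCMC settings on top of the model/prior configuration.

    The chain runs ``n_adapt`` warm-up sweeps with proposal-scale
    adaptation (targeting 30-45% acceptance), then ``n_iter`` fixed-kernel
    sweeps of which the first ``n_burn`` are discarded.
    """

    n_iter: int = 5000
    n_burn: int = 1000
    n_adapt: int = 1000
    n_chains: int = 3
    thin: int = 1
    seed: int = 0
    # initial proposal scales; None -> derived from the data at init time
    prop_s_marked: Optional[float] = None
    prop_s_aug: Optional[float] = None
    prop_sigma: float = 0.1
    prop_lam0_mark: float = 0.5
    prop_lam0_resight: float = 0.2
    sigma_init: Optional[float] = None
    save_z: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        if not (self.n_iter > self.n_burn >= 0):
            raise ValueError("need n_iter > n_burn >= 0")
        if self.n_adapt < 0 or self.thin < 1 or self.n_chains < 1:
            raise ValueError("bad MCMC settings")


@dataclass
class PosteriorSamples:
    """Posterior draws, one row block per chain (burn-in already removed).

    ``draws[name]`` has shape (n_chains, n_kept); density ``D = N / area``
    is derived. ``acceptance`` maps update-block names to pooled acceptance
    rates over the post-adaptation phase.
    """

    draws: dict
    area: float
    M: int
    m: int
    acceptance: dict
    config: MCMCConfig
    z_draws: Optional[np.ndarray] = None  # (n_chains, n_kept, M) when saved

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_kept(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def posterior_mean(self, name: str) -> float:
        return float(self.pooled(name).mean())

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per kept iteration per chain."""
        rows = []
        for c in range(self.n_chains):
            df = pd.DataFrame({k: self.draws[k][c] for k in PARAM_NAMES})
            df.insert(0, "iter", np.arange(self.n_kept))
            df.insert(0, "chain", c)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def delta_posterior(n_identified: float, n_unidentified: float, prior=(1.0, 1.0)):
    """Beta full-conditional of the identification probability delta.

    Under the marginalized model the conditional is free of every other
    parameter: the delta-dependence of the thinned Poisson means cancels
    between the identified and unidentified streams, leaving
    Beta(a + S_id, b + S_unid) where the S are the total identified and
    unidentified-marked event counts.
    """
    if n_identified < 0 or n_unidentified < 0:
        raise ValueError("event totals must be nonnegative")
    return (prior[0] + n_identified, prior[1] + n_unidentified)


def _telemetry_stats(dataset: SMRDataset):
    m = dataset.m
    tn = np.zeros(m)
    tmx = np.zeros(m)
    tmy = np.zeros(m)
    tss = np.zeros(m)
    for i, fixes in enumerate(dataset.telemetry):
        n = fixes.shape[0]
        tn[i] = n
        if n:
            mu = fixes.mean(axis=0)
            tmx[i], tmy[i] = mu
            tss[i] = float(((fixes - mu) ** 2).sum())
    return tn, tmx, tmy, tss


def pooled_telemetry_sd(dataset: SMRDataset) -> Optional[float]:
    """Pooled per-axis standard deviation of fixes around each individual's
    own centroid; None when there are no fixes."""
    tn, _, _, tss = _telemetry_stats(dataset)
    n_tot = tn.sum()
    if n_tot < 2:
        return None
    # tss sums squared deviations over both axes -> 2n terms
    return float(np.sqrt(tss.sum() / (2.0 * n_tot)))


def init_state(
    dataset: SMRDataset, config: MCMCConfig, rng: np.random.Generator
) -> AugmentedState:
    """Overdispersed but data-informed starting state.

    Marked centers start at the centroid of each individual's telemetry
    fixes and detections; sigma at the pooled telemetry standard deviation
    (override with ``config.sigma_init``); delta at its posterior mean under
    a uniform prior given the identified/unidentified event totals; the
    baseline rates at their prior midpoints.
    """
    m, M = dataset.m, config.M
    if M <= m:
        raise ValueError(f"augmentation size M={M} must exceed m={m}")
    space = dataset.state_space
    if space is None:
        raise ValueError("dataset needs a state space before fitting")

    sigma0 = config.sigma_init
    if sigma0 is None:
        sigma0 = pooled_telemetry_sd(dataset)
    if sigma0 is None:
        if m == 0:
            raise ValueError(
                "sigma is not identifiable without telemetry or marked "
                "individuals; provide config.sigma_init"
            )
        # fall back to half the mean nearest-neighbour camera spacing
        from scipy.spatial import cKDTree

        tree = cKDTree(dataset.cameras.coords)
        if dataset.cameras.J > 1:
            dd, _ = tree.query(dataset.cameras.coords, k=2)
            sigma0 = 0.5 * float(dd[:, 1].mean())
        else:
            sigma0 = 0.25 * max(space.width, space.height)
    sigma0 = min(max(sigma0, 1e-6), 0.99 * config.sigma_upper(space))

    s = space.sample_uniform(M, rng)
    for i in range(m):
        pts = [dataset.telemetry[i]] if dataset.telemetry[i].size else []
        cap_j = dataset.marking[i].sum(axis=1)  # captures per trap
        if cap_j.sum() > 0:
            pts.append(np.repeat(dataset.traps.coords, cap_j.astype(int), axis=0))
        yid_j = dataset.resight_identified[i].sum(axis=1)
        if yid_j.sum() > 0:
            pts.append(np.repeat(dataset.cameras.coords, yid_j.astype(int), axis=0))
        if pts:
            s[i] = np.vstack(pts).mean(axis=0)
    s[:m] = space.clip(s[:m])

    s_id = dataset.n_identified_events
    s_un = dataset.n_unidentified_marked_events
    a, b = delta_posterior(s_id, s_un)
    params = Parameters(
        lam0_mark=0.5 * config.lam0_mark_max,
        lam0_resight=0.5 * config.lam0_resight_max,
        sigma=float(sigma0),
        delta=a / (a + b),
        psi=0.5,
    )
    z = np.ones(M, dtype=int)
    z[m:] = (rng.random(M - m) < 0.5).astype(int)
    return AugmentedState(z=z, s=s, params=params, M=M, m=m)


def prepare_arrays(dataset: SMRDataset):
    """Sufficient-statistic arrays consumed by the jitted kernels."""
    m = dataset.m
    cap = dataset.marking.sum(axis=2)  # (m, Jm)
    ktrap = dataset.traps.occasions_on  # (Jm,)
    yid = dataset.resight_identified.sum(axis=2)  # (m, Jc)
    keff = np.einsum("jk,ik->ij", dataset.cameras.effort, dataset.alive)  # (m, Jc)
    kcam = dataset.cameras.occasions_on  # (Jc,)
    nun = dataset.unmarked_counts.sum(axis=1)  # (Jc,)
    tn, tmx, tmy, tss = _telemetry_stats(dataset)
    return {
        "Xt": np.ascontiguousarray(dataset.traps.coords),
        "ktrap": np.ascontiguousarray(ktrap, dtype=float),
        "cap": np.ascontiguousarray(cap, dtype=float),
        "Xc": np.ascontiguousarray(dataset.cameras.coords),
        "kcam": np.ascontiguousarray(kcam, dtype=float),
        "effcam": np.ascontiguousarray(dataset.cameras.effort, dtype=float),
        "yid": np.ascontiguousarray(yid, dtype=float),
        "keff": np.ascontiguousarray(keff, dtype=float),
        "alive": np.ascontiguousarray(dataset.alive, dtype=float),
        "nnid": np.ascontiguousarray(dataset.unid_marked_counts, dtype=float),
        "nun": np.ascontiguousarray(nun, dtype=float),
        "tn": tn,
        "tmx": tmx,
        "tmy": tmy,
        "tss": tss,
    }


# ---------------------------------------------------------------------------
# single-update reference functions
#
# These perform one update of one block, delegating to the same jitted
# target functions the chain kernel uses. They exist for interactive use
# and for tests that pin the update math to the reference joint density;
# run_mcmc is the production path.


def _caches(dataset: SMRDataset, state: AugmentedState):
    arrays = prepare_arrays(dataset)
    sig = state.params.sigma
    d2t = np.stack(
        [_kernels._sqdist_row(x, y, arrays["Xt"]) for x, y in state.s]
    )
    d2c = np.stack(
        [_kernels._sqdist_row(x, y, arrays["Xc"]) for x, y in state.s]
    )
    return arrays, _kernels._expmat(d2t, sig), _kernels._expmat(d2c, sig)


def update_activity_center(
    i: int,
    state: AugmentedState,
    dataset: SMRDataset,
    rng: np.random.Generator,
    scale: float = 0.05,
) -> AugmentedState:
    """One Metropolis (or prior-refresh) update of center s_i, in place."""
    a, Et, Ec = _caches(dataset, state)
    p = state.params
    space = dataset.state_space
    m = dataset.m
    if i >= m and state.z[i] == 0:
        state.s[i] = space.sample_uniform(1, rng)[0]
        return state
    prop = state.s[i] + scale * rng.standard_normal(2)
    if not space.contains(prop[None, :]).all():
        return state
    if i < m:
        sa = _kernels._build_sa(Ec, a["alive"], m)
        sa_oth = sa - a["alive"][i][None, :] * Ec[i][:, None]

        def target(sx, sy):
            return _kernels.marked_s_logtarget(
                sx, sy, a["cap"][i], a["yid"][i], a["keff"][i], a["alive"][i],
                sa_oth, a["nnid"], a["effcam"], a["Xt"], a["ktrap"], a["Xc"],
                p.lam0_mark, p.lam0_resight, p.sigma, p.delta,
                a["tn"][i], a["tmx"][i], a["tmy"][i], a["tss"][i],
                False, False, np.zeros(dataset.cameras.J),
            )

    else:
        g = _kernels._build_g(Ec, state.z.astype(np.int64), m)
        g_oth = np.maximum(g - Ec[i], 0.0)

        def target(sx, sy):
            return _kernels.aug_s_logtarget(
                sx, sy, g_oth, a["nun"], a["kcam"], a["Xt"], a["ktrap"],
                a["Xc"], p.lam0_mark, p.lam0_resight, p.sigma, False,
            )

    dl = target(*prop) - target(*state.s[i])
    if np.isfinite(dl) and np.log(rng.random()) < dl:
        state.s[i] = prop
    return state


def update_z(
    i: int, state: AugmentedState, dataset: SMRDataset, rng: np.random.Generator
) -> AugmentedState:
    """Gibbs update of the inclusion indicator of augmented slot i > m."""
    m = dataset.m
    if i < m:
        raise ValueError("z is fixed at 1 for marked individuals")
    a, _Et, Ec = _caches(dataset, state)
    p = state.params
    z1 = state.z.copy()
    z1[i] = 1
    g = _kernels._build_g(Ec, z1.astype(np.int64), m)
    g_oth = np.maximum(g - Ec[i], 0.0)
    ll1 = _kernels.aug_s_logtarget(
        state.s[i, 0], state.s[i, 1], g_oth, a["nun"], a["kcam"],
        a["Xt"], a["ktrap"], a["Xc"], p.lam0_mark, p.lam0_resight, p.sigma,
        False,
    )
    ll0 = _kernels._ll_unmarked(g_oth, a["nun"], a["kcam"], p.lam0_resight)
    if p.psi <= 0.0:
        p1 = 0.0
    elif not np.isfinite(ll0):
        p1 = 1.0
    else:
        logodds = np.log(p.psi) - np.log1p(-p.psi) + ll1 - ll0
        p1 = 1.0 / (1.0 + np.exp(-logodds))
    state.z[i] = int(rng.random() < p1)
    return state


def update_psi(state: AugmentedState, rng: np.random.Generator) -> float:
    """Conjugate draw psi ~ Beta(1 + sum z, 1 + M - sum z), in place."""
    nz = int(state.z.sum())
    state.params.psi = float(rng.beta(1.0 + nz, 1.0 + state.M - nz))
    return state.params.psi


def update_delta(
    state: AugmentedState, dataset: SMRDataset, rng: np.random.Generator
) -> float:
    """Conjugate draw of the identification probability, in place.

    Free of every other parameter under the marginalized likelihood.
    """
    a, b = delta_posterior(
        dataset.n_identified_events, dataset.n_unidentified_marked_events
    )
    state.params.delta = float(rng.beta(a, b))
    return state.params.delta


def update_rate_params(
    state: AugmentedState,
    dataset: SMRDataset,
    rng: np.random.Generator,
    scales=(0.5, 0.2, 0.1),
    config: ModelConfig | None = None,
) -> Parameters:
    """One Metropolis block each for lam0_mark (logit scale), lam0_resight
    and sigma (log scale, with Jacobians), in place."""
    config = config or ModelConfig()
    a, Et, Ec = _caches(dataset, state)
    m = dataset.m
    sigma_hi = config.sigma_upper(dataset.state_space)

    def full(params, Etx, Ecx):
        return _kernels.full_loglik(
            state.s, state.z.astype(np.int64), Etx, Ecx, a["cap"], a["ktrap"],
            a["yid"], a["keff"], a["alive"], a["nnid"], a["effcam"],
            a["nun"], a["kcam"], a["tn"], a["tmx"], a["tmy"], a["tss"],
            params.lam0_mark, params.lam0_resight, params.sigma,
            params.delta, m, config.marking_model == "cloglog", False,
            np.zeros((max(m, 1), dataset.cameras.J)),
        )

    p = state.params
    # lam0_mark on the logit scale
    hi = config.lam0_mark_max
    logit = np.log(p.lam0_mark / (hi - p.lam0_mark))
    cand = hi / (1.0 + np.exp(-(logit + scales[0] * rng.standard_normal())))
    if 0.0 < cand < hi:
        new = Parameters(cand, p.lam0_resight, p.sigma, p.delta, p.psi)
        jac = np.log(cand * (hi - cand)) - np.log(p.lam0_mark * (hi - p.lam0_mark))
        if np.log(rng.random()) < full(new, Et, Ec) - full(p, Et, Ec) + jac:
            p.lam0_mark = cand
    # lam0_resight on the log scale
    cand = p.lam0_resight * np.exp(scales[1] * rng.standard_normal())
    if 0.0 < cand < config.lam0_resight_max:
        new = Parameters(p.lam0_mark, cand, p.sigma, p.delta, p.psi)
        jac = np.log(cand) - np.log(p.lam0_resight)
        if np.log(rng.random()) < full(new, Et, Ec) - full(p, Et, Ec) + jac:
            p.lam0_resight = cand
    # sigma on the log scale (kernel caches rebuilt at the candidate)
    cand = p.sigma * np.exp(scales[2] * rng.standard_normal())
    if 0.0 < cand < sigma_hi:
        new = Parameters(p.lam0_mark, p.lam0_resight, cand, p.delta, p.psi)
        _a2, Et2, Ec2 = _caches(
            dataset,
            AugmentedState(z=state.z, s=state.s, params=new, M=state.M, m=m),
        )
        jac = np.log(cand) - np.log(p.sigma)
        if np.log(rng.random()) < full(new, Et2, Ec2) - full(p, Et, Ec) + jac:
            p.sigma = cand
    return p


def _run(dataset: SMRDataset, config: MCMCConfig, latent: bool) -> PosteriorSamples:
    dataset.validate()
    space = dataset.state_space
    if space is None:
        raise ValueError("dataset needs a state space before fitting")
    arrays = prepare_arrays(dataset)
    m, M = dataset.m, config.M
    sigma_hi = config.sigma_upper(space)

    n_sweeps = config.n_adapt + config.n_iter
    n_discard = config.n_adapt + config.n_burn
    n_kept = int(np.ceil((config.n_iter - config.n_burn) / config.thin))

    draws = {k: np.empty((config.n_chains, n_kept)) for k in PARAM_NAMES}
    z_all = (
        np.empty((config.n_chains, n_kept, M), dtype=np.int8)
        if config.save_z
        else None
    )
    acc_total = np.zeros((5, 2))

    for c in range(config.n_chains):
        chain_seed = int((config.seed + 1_000_003 * c) % (2**31 - 1))
        rng = np.random.default_rng(chain_seed)
        state = init_state(dataset, config, rng)
        ps_sm = config.prop_s_marked or max(0.5 * state.params.sigma, 1e-4)
        ps_sa = config.prop_s_aug or 0.25 * max(space.width, space.height)

        out = np.empty((n_kept, 6))
        out_z = np.empty((n_kept, M), dtype=np.int8)
        acc = np.zeros((5, 2))
        status = _kernels.run_chain(
            chain_seed,
            n_sweeps,
            n_discard,
            config.thin,
            config.n_adapt,
            latent,
            arrays["Xt"],
            arrays["ktrap"],
            arrays["cap"],
            arrays["Xc"],
            arrays["kcam"],
            arrays["effcam"],
            arrays["yid"],
            arrays["keff"],
            arrays["alive"],
            arrays["nnid"],
            arrays["nun"],
            arrays["tn"],
            arrays["tmx"],
            arrays["tmy"],
            arrays["tss"],
            space.xmin,
            space.xmax,
            space.ymin,
            space.ymax,
            config.lam0_mark_max,
            config.lam0_resight_max,
            sigma_hi,
            config.marking_model == "cloglog",
            state.s,
            state.z,
            state.params.lam0_mark,
            state.params.lam0_resight,
            state.params.sigma,
            state.params.delta,
            state.params.psi,
            m,
            ps_sm,
            ps_sa,
            config.prop_lam0_mark,
            config.prop_lam0_resight,
            config.prop_sigma,
            out,
            out_z,
            acc,
        )
        if status != 0:
            raise RuntimeError(
                f"chain {c}: non-finite joint density encountered (check that "
                "the data are consistent with the model, e.g. no counts at "
                "cells whose mean is structurally zero)"
            )
        for k, name in enumerate(PARAM_NAMES[:6]):
            draws[name][c] = out[:, k]
        draws["D"][c] = out[:, 5] / space.area
        if config.save_z:
            z_all[c] = out_z
        acc_total += acc

    acceptance = {
        name: (acc_total[b, 1] / acc_total[b, 0] if acc_total[b, 0] else np.nan)
        for b, name in enumerate(
            ("s_marked", "s_augmented", "lam0_mark", "lam0_resight", "sigma")
        )
    }
    samples = PosteriorSamples(
        draws=draws,
        area=space.area,
        M=M,
        m=m,
        acceptance=acceptance,
        config=config,
        z_draws=z_all,
    )
    frac_at_M = float((samples.pooled("N") >= M).mean())
    if frac_at_M > 0.01:
        warnings.warn(
            f"{100 * frac_at_M:.1f}% of posterior draws have N = M; "
            "the augmentation size M is too small and truncates the posterior",
            RuntimeWarning,
            stacklevel=2,
        )
    return samples


def run_mcmc(dataset: SMRDataset, config: MCMCConfig) -> PosteriorSamples:
    """Fit the model with the marginalized (default) sampler.

    Deterministic given (dataset, config, config.seed): identical seeds give
    identical chains.
    """
    return _run(dataset, config, latent=False)


def run_mcmc_latent(dataset: SMRDataset, config: MCMCConfig) -> PosteriorSamples:
    """Fit with the latent-imputation sampler (independent cross-check).

    The per-individual unidentified histories are drawn each sweep from
    their exact multinomial full conditional given the observed cell sums,
    and the conditional Poisson likelihood replaces the marginalized one.
    """
    return _run(dataset, config, latent=True)
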