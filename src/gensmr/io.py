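"""CSV dataset schemas, run configuration, state-space construction and the
two-pass fitting workflow.

Dataset directory layout (comma-separated, header row, UTF-8):

* ``detectors.csv``: detector_id, kind (marking_trap|camera), x, y
* ``effort.csv``: detector_id, occasion, on  (occasions 1-based per kind)
* ``marking.csv``: individual_id, trap_id, occasion, captured
* ``resight_identified.csv``: individual_id, camera_id, occasion, count
* ``counts.csv``: camera_id, occasion, n_unid_marked, n_unmarked
* ``telemetry.csv``: individual_id, x, y
* ``alive.csv``: individual_id, occasion, alive

Coordinates are planar Cartesian in one consistent unit (km for field
data); density is reported per squared unit. The individual_id universe of
``marking.csv``/``alive.csv`` defines the marked population; zero rows may
be omitted everywhere (sparse encoding).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, fields as dc_fields
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    CAMERA,
    MARKING_TRAP,
    DetectorArray,
    ModelConfig,
    SMRDataset,
    StateSpace,
)
from .sampler import (
    MCMCConfig,
    PosteriorSamples,
    pooled_telemetry_sd,
    run_mcmc,
)

__all__ = [
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "build_state_space",
    "two_pass_fit",
    "write_samples_csv",
]

_FILES = (
    "detectors.csv",
    "effort.csv",
    "marking.csv",
    "resight_identified.csv",
    "counts.csv",
    "telemetry.csv",
    "alive.csv",
)


@dataclass
class RunConfig:
    """Flat key-value run configuration (see :meth:`from_file`)."""

    data_dir: str = "."
    out_dir: str = "out"
    seed: int = 0
    M: int = 150
    n_iter: int = 5000
    n_burn: int = 1000
    n_adapt: int = 1000
    n_chains: int = 3
    thin: int = 1
    buffer_mult: float = 2.5
    marking_model: str = "bernoulli"
    sigma_init: Optional[float] = None
    sigma_max: Optional[float] = None
    lam0_mark_max: float = 1.0
    lam0_resight_max: float = 2.0

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Parse a ``key = value`` text file; '#' starts a comment.

        Unknown keys are rejected (typo safety).
        """
        known = {f.name: f for f in dc_fields(cls)}
        values = {}
        with open(path) as fh:
            for ln, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{ln}: expected 'key = value'")
                key, val = (part.strip() for part in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
                values[key] = val
        cfg = cls()
        for key, val in values.items():
            current = getattr(cfg, key)
            if key in ("sigma_init", "sigma_max"):
                setattr(cfg, key, None if val.lower() == "none" else float(val))
            elif isinstance(current, bool):
                setattr(cfg, key, val.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(val))
            elif isinstance(current, float):
                setattr(cfg, key, float(val))
            else:
                setattr(cfg, key, val)
        return cfg

    def mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(
            M=self.M,
            n_iter=self.n_iter,
            n_burn=self.n_burn,
            n_adapt=self.n_adapt,
            n_chains=self.n_chains,
            thin=self.thin,
            seed=self.seed,
            buffer_mult=self.buffer_mult,
            marking_model=self.marking_model,
            sigma_init=self.sigma_init,
            sigma_max=self.sigma_max,
            lam0_mark_max=self.lam0_mark_max,
            lam0_resight_max=self.lam0_resight_max,
        )


def build_state_space(
    detector_coords: np.ndarray, sigma_hat: float, multiplier: float = 2.5
) -> StateSpace:
    """Detector envelope expanded by ``multiplier * sigma_hat`` per side."""
    if sigma_hat <= 0:
        raise ValueError("sigma_hat must be positive")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    c = np.atleast_2d(np.asarray(detector_coords, dtype=float))
    if c.shape[0] < 1:
        raise ValueError("need at least one detector")
    buf = multiplier * sigma_hat
    return StateSpace(
        xmin=float(c[:, 0].min() - buf),
        xmax=float(c[:, 0].max() + buf),
        ymin=float(c[:, 1].min() - buf),
        ymax=float(c[:, 1].max() + buf),
    )


def write_dataset(dataset: SMRDataset, out_dir: str) -> None:
    """Write a dataset to the CSV schema (sparse: zero rows omitted)."""
    os.makedirs(out_dir, exist_ok=True)
    m = dataset.m
    ids = dataset.individual_ids or [f"ind_{i + 1:03d}" for i in range(m)]
    trap_ids = [f"trap_{j + 1:03d}" for j in range(dataset.traps.J)]
    cam_ids = [f"cam_{j + 1:03d}" for j in range(dataset.cameras.J)]

    det = []
    for jid, (x, y) in zip(trap_ids, dataset.traps.coords):
        det.append((jid, MARKING_TRAP, x, y))
    for jid, (x, y) in zip(cam_ids, dataset.cameras.coords):
        det.append((jid, CAMERA, x, y))
    pd.DataFrame(det, columns=["detector_id", "kind", "x", "y"]).to_csv(
        os.path.join(out_dir, "detectors.csv"), index=False
    )

    eff = []
    for det_ids, arr in ((trap_ids, dataset.traps), (cam_ids, dataset.cameras)):
        for j, jid in enumerate(det_ids):
            for k in range(arr.K):
                eff.append((jid, k + 1, int(arr.effort[j, k])))
    pd.DataFrame(eff, columns=["detector_id", "occasion", "on"]).to_csv(
        os.path.join(out_dir, "effort.csv"), index=False
    )

    rows = np.argwhere(dataset.marking > 0)
    pd.DataFrame(
        [(ids[i], trap_ids[j], k + 1, 1) for i, j, k in rows],
        columns=["individual_id", "trap_id", "occasion", "captured"],
    ).to_csv(os.path.join(out_dir, "marking.csv"), index=False)

    rows = np.argwhere(dataset.resight_identified > 0)
    pd.DataFrame(
        [
            (ids[i], cam_ids[j], k + 1, int(dataset.resight_identified[i, j, k]))
            for i, j, k in rows
        ],
        columns=["individual_id", "camera_id", "occasion", "count"],
    ).to_csv(os.path.join(out_dir, "resight_identified.csv"), index=False)

    rows = np.argwhere((dataset.unid_marked_counts + dataset.unmarked_counts) > 0)
    pd.DataFrame(
        [
            (
                cam_ids[j],
                k + 1,
                int(dataset.unid_marked_counts[j, k]),
                int(dataset.unmarked_counts[j, k]),
            )
            for j, k in rows
        ],
        columns=["camera_id", "occasion", "n_unid_marked", "n_unmarked"],
    ).to_csv(os.path.join(out_dir, "counts.csv"), index=False)

    tel = []
    for i, fixes in enumerate(dataset.telemetry):
        for x, y in fixes:
            tel.append((ids[i], x, y))
    pd.DataFrame(tel, columns=["individual_id", "x", "y"]).to_csv(
        os.path.join(out_dir, "telemetry.csv"), index=False
    )

    al = []
    for i in range(m):
        for k in range(dataset.alive.shape[1]):
            al.append((ids[i], k + 1, int(dataset.alive[i, k])))
    pd.DataFrame(al, columns=["individual_id", "occasion", "alive"]).to_csv(
        os.path.join(out_dir, "alive.csv"), index=False
    )


def _read_csv(data_dir: str, name: str, columns) -> pd.DataFrame:
    path = os.path.join(data_dir, name)
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing input file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def _index_map(values) -> dict:
    return {v: i for i, v in enumerate(values)}


def read_dataset(data_dir) -> SMRDataset:
    """Load and validate a dataset directory; errors name file and row.

    Accepts a directory path or a :class:`RunConfig` (whose ``data_dir`` is
    used). The returned dataset has no state space yet (that is built from
    a sigma estimate; see :func:`two_pass_fit`).
    """
    if isinstance(data_dir, RunConfig):
        data_dir = data_dir.data_dir
    det = _read_csv(data_dir, "detectors.csv", ["detector_id", "kind", "x", "y"])
    bad = det[~det["kind"].isin([MARKING_TRAP, CAMERA])]
    if len(bad):
        raise ValueError(
            f"detectors.csv row {bad.index[0] + 2}: unknown kind "
            f"{bad['kind'].iloc[0]!r}"
        )
    traps_df = det[det["kind"] == MARKING_TRAP].reset_index(drop=True)
    cams_df = det[det["kind"] == CAMERA].reset_index(drop=True)
    if len(traps_df) == 0 or len(cams_df) == 0:
        raise ValueError("detectors.csv: need at least one trap and one camera")
    trap_ix = _index_map(traps_df["detector_id"])
    cam_ix = _index_map(cams_df["detector_id"])

    eff = _read_csv(data_dir, "effort.csv", ["detector_id", "occasion", "on"])
    K_mark = int(eff[eff["detector_id"].isin(trap_ix)]["occasion"].max())
    K_res = int(eff[eff["detector_id"].isin(cam_ix)]["occasion"].max())
    eff_t = np.zeros((len(traps_df), K_mark))
    eff_c = np.zeros((len(cams_df), K_res))
    for row_no, r in enumerate(eff.itertuples(index=False), start=2):
        if r.detector_id in trap_ix:
            eff_t[trap_ix[r.detector_id], int(r.occasion) - 1] = r.on
        elif r.detector_id in cam_ix:
            eff_c[cam_ix[r.detector_id], int(r.occasion) - 1] = r.on
        else:
            raise ValueError(f"effort.csv row {row_no}: unknown detector {r.detector_id!r}")

    traps = DetectorArray(traps_df[["x", "y"]].to_numpy(), MARKING_TRAP, eff_t)
    cameras = DetectorArray(cams_df[["x", "y"]].to_numpy(), CAMERA, eff_c)

    alive_df = _read_csv(data_dir, "alive.csv", ["individual_id", "occasion", "alive"])
    mark_df = _read_csv(
        data_dir, "marking.csv", ["individual_id", "trap_id", "occasion", "captured"]
    )
    ids = sorted(set(alive_df["individual_id"]) | set(mark_df["individual_id"]))
    ind_ix = _index_map(ids)
    m = len(ids)

    alive = np.ones((m, K_res))
    for row_no, r in enumerate(alive_df.itertuples(index=False), start=2):
        alive[ind_ix[r.individual_id], int(r.occasion) - 1] = r.alive

    marking = np.zeros((m, len(traps_df), K_mark))
    for row_no, r in enumerate(mark_df.itertuples(index=False), start=2):
        if r.trap_id not in trap_ix:
            raise ValueError(f"marking.csv row {row_no}: unknown trap {r.trap_id!r}")
        marking[ind_ix[r.individual_id], trap_ix[r.trap_id], int(r.occasion) - 1] = (
            r.captured
        )

    rid_df = _read_csv(
        data_dir,
        "resight_identified.csv",
        ["individual_id", "camera_id", "occasion", "count"],
    )
    resight = np.zeros((m, len(cams_df), K_res))
    for row_no, r in enumerate(rid_df.itertuples(index=False), start=2):
        if r.individual_id not in ind_ix:
            raise ValueError(
                f"resight_identified.csv row {row_no}: unknown individual "
                f"{r.individual_id!r}"
            )
        if r.camera_id not in cam_ix:
            raise ValueError(
                f"resight_identified.csv row {row_no}: unknown camera {r.camera_id!r}"
            )
        resight[ind_ix[r.individual_id], cam_ix[r.camera_id], int(r.occasion) - 1] = (
            r.count
        )

    cnt_df = _read_csv(
        data_dir, "counts.csv", ["camera_id", "occasion", "n_unid_marked", "n_unmarked"]
    )
    nnid = np.zeros((len(cams_df), K_res))
    nun = np.zeros((len(cams_df), K_res))
    for row_no, r in enumerate(cnt_df.itertuples(index=False), start=2):
        if r.camera_id not in cam_ix:
            raise ValueError(f"counts.csv row {row_no}: unknown camera {r.camera_id!r}")
        j, k = cam_ix[r.camera_id], int(r.occasion) - 1
        if eff_c[j, k] == 0 and (r.n_unid_marked > 0 or r.n_unmarked > 0):
            raise ValueError(
                f"counts.csv row {row_no}: count at zero-effort camera-occasion "
                f"({r.camera_id!r}, occasion {r.occasion})"
            )
        nnid[j, k] = r.n_unid_marked
        nun[j, k] = r.n_unmarked

    tel_df = _read_csv(data_dir, "telemetry.csv", ["individual_id", "x", "y"])
    telemetry = [np.empty((0, 2)) for _ in range(m)]
    for iid, grp in tel_df.groupby("individual_id"):
        if iid not in ind_ix:
            raise ValueError(f"telemetry.csv: unknown individual {iid!r}")
        telemetry[ind_ix[iid]] = grp[["x", "y"]].to_numpy(dtype=float)

    ds = SMRDataset(
        traps=traps,
        cameras=cameras,
        marking=marking,
        resight_identified=resight,
        unid_marked_counts=nnid,
        unmarked_counts=nun,
        telemetry=telemetry,
        alive=alive,
        state_space=None,
        individual_ids=ids,
    )
    ds.validate()
    return ds


def two_pass_fit(
    dataset: SMRDataset, config: MCMCConfig, log=None
) -> PosteriorSamples:
    """Fit twice, rebuilding the state space from the first pass's sigma.

    Pass 1 buffers the detector envelope with ``buffer_mult`` times a
    provisional sigma (the pooled telemetry standard deviation, or
    ``config.sigma_init``); pass 2 rebuilds S with the pass-1 posterior
    mean of sigma and refits. Returns the pass-2 samples; both buffers are
    recorded on the result as ``.info``.
    """
    sigma0 = config.sigma_init or pooled_telemetry_sd(dataset)
    if sigma0 is None:
        raise ValueError(
            "no telemetry and no sigma_init: cannot build a provisional state space"
        )
    coords = dataset.detector_coords()
    dataset.state_space = build_state_space(coords, sigma0, config.buffer_mult)
    if log:
        log(f"pass 1: provisional sigma={sigma0:.4f} "
            f"buffer={config.buffer_mult * sigma0:.4f} area={dataset.state_space.area:.4f}")
    pass1 = run_mcmc(dataset, config)
    sigma1 = pass1.posterior_mean("sigma")
    dataset.state_space = build_state_space(coords, sigma1, config.buffer_mult)
    if log:
        log(f"pass 2: posterior-mean sigma={sigma1:.4f} "
            f"buffer={config.buffer_mult * sigma1:.4f} area={dataset.state_space.area:.4f}")
    pass2 = run_mcmc(dataset, config)
    pass2.info = {
        "sigma_provisional": float(sigma0),
        "sigma_pass1": float(sigma1),
        "buffer_pass1": float(config.buffer_mult * sigma0),
        "buffer_pass2": float(config.buffer_mult * sigma1),
        "area_pass2": float(dataset.state_space.area),
    }
    return pass2


def write_samples_csv(samples: PosteriorSamples, path: str) -> None:
    samples.to_dataframe().to_csv(path, index=False)
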