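"""Domain types for generalized spatial mark-resight with incomplete identification.

The model estimates animal abundance/density from three coupled data streams
collected on a planar state space:

* a *marking* phase: live traps produce binary capture histories for the
  ``m`` individuals that end up marked;
* a *resighting* phase: camera traps produce per-occasion counts, split into
  identified-marked (per individual), marked-but-unidentified, and unmarked
  detections;
* *telemetry*: GPS fixes on marked individuals that pin down the spatial
  scale of movement.

Every individual (real or augmented) carries a latent activity center
``s_i`` distributed uniformly over the state space; detection decays with
distance from the center through a half-normal kernel with scale ``sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StateSpace",
    "DetectorArray",
    "Parameters",
    "SMRDataset",
    "AugmentedState",
    "ModelConfig",
]


@dataclass(frozen=True)
class StateSpace:
    """Rectangular region S assumed to contain every activity center.

    Coordinates are planar Cartesian in an arbitrary (but consistent) length
    unit; density is reported per squared unit of this system.
    """

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                f"degenerate state space: [{self.xmin}, {self.xmax}] x "
                f"[{self.ymin}, {self.ymax}]"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of which ``(n, 2)`` points fall inside S."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (pts[:, 0] >= self.xmin)
            & (pts[:, 0] <= self.xmax)
            & (pts[:, 1] >= self.ymin)
            & (pts[:, 1] <= self.ymax)
        )

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. uniform points from S as an ``(n, 2)`` array."""
        out = np.empty((n, 2), dtype=float)
        out[:, 0] = rng.uniform(self.xmin, self.xmax, size=n)
        out[:, 1] = rng.uniform(self.ymin, self.ymax, size=n)
        return out

    def clip(self, points: np.ndarray) -> np.ndarray:
        pts = np.array(np.atleast_2d(points), dtype=float)
        pts[:, 0] = np.clip(pts[:, 0], self.xmin, self.xmax)
        pts[:, 1] = np.clip(pts[:, 1], self.ymin, self.ymax)
        return pts


MARKING_TRAP = "marking_trap"
CAMERA = "camera"


@dataclass
class DetectorArray:
    """A set of detectors of one kind with a binary effort matrix.

    Parameters
    ----------
    coords : (J, 2) array
        Cartesian detector locations.
    kind : {"marking_trap", "camera"}
    effort : (J, K) array of {0, 1}
        1 where detector j was operational on occasion k. A column of all
        zeros (an occasion with no effort anywhere) is allowed.
    """

    coords: np.ndarray
    kind: str
    effort: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.effort = np.atleast_2d(np.asarray(self.effort, dtype=float))
        if self.kind not in (MARKING_TRAP, CAMERA):
            raise ValueError(f"unknown detector kind {self.kind!r}")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (J, 2)")
        if self.coords.shape[0] < 1:
            raise ValueError("need at least one detector")
        if self.effort.shape[0] != self.coords.shape[0]:
            raise ValueError(
                f"effort has {self.effort.shape[0]} rows for "
                f"{self.coords.shape[0]} detectors"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite detector coordinate")
        if not np.isin(self.effort, (0.0, 1.0)).all():
            raise ValueError("effort entries must be binary")

    @property
    def J(self) -> int:
        return self.coords.shape[0]

    @property
    def K(self) -> int:
        return self.effort.shape[1]

    @property
    def occasions_on(self) -> np.ndarray:
        """Per-detector count of operational occasions, shape (J,)."""
        return self.effort.sum(axis=1)


@dataclass
class Parameters:
    """Scalar parameters of the joint model.

    lam0_mark
        Baseline per-occasion capture probability in the marking process
        (Bernoulli observation model; uniform prior on (0, 1)).
    lam0_resight
        Baseline resighting rate of the Poisson encounter model
        (uniform prior on (0, 2)).
    sigma
        Half-normal spatial scale shared by marking, resighting and
        telemetry (same length unit as the coordinates).
    delta
        Probability that a detected marked individual is individually
        identified.
    psi
        Data-augmentation inclusion probability; N ~ Binomial(M, psi).
    """

    lam0_mark: float
    lam0_resight: float
    sigma: float
    delta: float
    psi: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.lam0_mark, self.lam0_resight, self.sigma, self.delta, self.psi]
        )

    def validate(self, config: "ModelConfig", state_space: Optional[StateSpace] = None) -> None:
        if not (0.0 <= self.lam0_mark <= config.lam0_mark_max):
            raise ValueError(f"lam0_mark={self.lam0_mark} outside prior support")
        if not (0.0 <= self.lam0_resight <= config.lam0_resight_max):
            raise ValueError(f"lam0_resight={self.lam0_resight} outside prior support")
        if self.sigma <= 0.0:
            raise ValueError("sigma must be positive")
        if state_space is not None and self.sigma > config.sigma_upper(state_space):
            raise ValueError("sigma outside prior support")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0, 1]")
        if not (0.0 <= self.psi <= 1.0):
            raise ValueError("psi must lie in [0, 1]")


@dataclass
class ModelConfig:
    """Model-structure and prior settings (shared by likelihoods and sampler).

    ``sigma_max=None`` resolves at fit time to half the longer side of the
    state space, which comfortably covers any home range that the design can
    inform.
    """

    lam0_mark_max: float = 1.0
    lam0_resight_max: float = 2.0
    sigma_max: Optional[float] = None
    marking_model: str = "bernoulli"  # or "cloglog"
    buffer_mult: float = 2.5
    M: int = 150

    def __post_init__(self) -> None:
        if self.marking_model not in ("bernoulli", "cloglog"):
            raise ValueError(f"unknown marking model {self.marking_model!r}")
        if self.buffer_mult <= 0:
            raise ValueError("buffer multiplier must be positive")

    def sigma_upper(self, state_space: StateSpace) -> float:
        if self.sigma_max is not None:
            return self.sigma_max
        return 0.5 * max(state_space.width, state_space.height)


@dataclass
class SMRDataset:
    """All observed data for one study.

    Array shapes (m marked individuals, J_mark traps over K_mark occasions,
    J_cam cameras over K_res occasions):

    * ``marking``: (m, J_mark, K_mark) binary capture histories w_ijk.
    * ``resight_identified``: (m, J_cam, K_res) identified-resight counts.
    * ``unid_marked_counts``: (J_cam, K_res) counts of marked-but-unidentified
      detections (nnid_jk).
    * ``unmarked_counts``: (J_cam, K_res) counts of unmarked detections.
    * ``telemetry``: length-m list of (n_i, 2) fix arrays (possibly empty).
    * ``alive``: (m, K_res) binary availability of each marked individual on
      each resighting occasion (0 after a known death).
    """

    traps: DetectorArray
    cameras: DetectorArray
    marking: np.ndarray
    resight_identified: np.ndarray
    unid_marked_counts: np.ndarray
    unmarked_counts: np.ndarray
    telemetry: list
    alive: np.ndarray
    state_space: Optional[StateSpace] = None
    individual_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.marking = np.asarray(self.marking, dtype=float)
        self.resight_identified = np.asarray(self.resight_identified, dtype=float)
        self.unid_marked_counts = np.asarray(self.unid_marked_counts, dtype=float)
        self.unmarked_counts = np.asarray(self.unmarked_counts, dtype=float)
        self.alive = np.asarray(self.alive, dtype=float)
        self.telemetry = [
            np.asarray(t, dtype=float).reshape(-1, 2) for t in self.telemetry
        ]

    @property
    def m(self) -> int:
        return self.marking.shape[0]

    @property
    def n_identified_events(self) -> float:
        return float(self.resight_identified.sum())

    @property
    def n_unidentified_marked_events(self) -> float:
        return float(self.unid_marked_counts.sum())

    def validate(self) -> None:
        """Check every structural invariant; raise ValueError with a
        descriptive message on the first violation."""
        m = self.m
        Jm, Km = self.traps.J, self.traps.K
        Jc, Kr = self.cameras.J, self.cameras.K
        if self.marking.shape != (m, Jm, Km):
            raise ValueError(
                f"marking shape {self.marking.shape} != ({m}, {Jm}, {Km})"
            )
        if self.resight_identified.shape != (m, Jc, Kr):
            raise ValueError(
                f"resight_identified shape {self.resight_identified.shape} "
                f"!= ({m}, {Jc}, {Kr})"
            )
        if self.unid_marked_counts.shape != (Jc, Kr):
            raise ValueError("unid_marked_counts shape mismatch")
        if self.unmarked_counts.shape != (Jc, Kr):
            raise ValueError("unmarked_counts shape mismatch")
        if self.alive.shape != (m, Kr):
            raise ValueError(f"alive shape {self.alive.shape} != ({m}, {Kr})")
        if len(self.telemetry) != m:
            raise ValueError(
                f"telemetry has {len(self.telemetry)} entries for m={m}"
            )
        for arr, name in (
            (self.marking, "marking"),
            (self.resight_identified, "resight_identified"),
            (self.unid_marked_counts, "unid_marked_counts"),
            (self.unmarked_counts, "unmarked_counts"),
        ):
            if (arr < 0).any():
                raise ValueError(f"negative entry in {name}")
            if not np.equal(np.mod(arr, 1), 0).all():
                raise ValueError(f"non-integer entry in {name}")
        if not np.isin(self.marking, (0.0, 1.0)).all():
            raise ValueError("marking histories must be binary")
        if not np.isin(self.alive, (0.0, 1.0)).all():
            raise ValueError("alive matrix must be binary")
        # counts are impossible wherever effort (or availability) is zero
        eff_m = self.traps.effort[None, :, :]
        if (self.marking * (1.0 - eff_m)).any():
            raise ValueError("marking capture recorded at a zero-effort trap-occasion")
        eff_c = self.cameras.effort
        avail = eff_c[None, :, :] * self.alive[:, None, :]
        if (self.resight_identified * (1.0 - avail)).any():
            raise ValueError(
                "identified resight recorded for a dead individual or "
                "zero-effort camera-occasion"
            )
        if (self.unid_marked_counts * (1.0 - eff_c)).any():
            raise ValueError("unidentified-marked count at a zero-effort camera-occasion")
        if (self.unmarked_counts * (1.0 - eff_c)).any():
            raise ValueError("unmarked count at a zero-effort camera-occasion")
        for i, t in enumerate(self.telemetry):
            if t.size and not np.isfinite(t).all():
                raise ValueError(f"non-finite telemetry fix for individual {i}")
        if self.state_space is not None:
            for det in (self.traps, self.cameras):
                if not self.state_space.contains(det.coords).all():
                    raise ValueError(f"{det.kind} coordinates outside the state space")

    def detector_coords(self) -> np.ndarray:
        return np.vstack([self.traps.coords, self.cameras.coords])


@dataclass
class AugmentedState:
    """Current latent state of the augmented model.

    The first ``m`` slots are the marked (real) individuals with z fixed at 1;
    slots m..M-1 are augmented pseudo-individuals whose inclusion indicator z
    is sampled.
    """

    z: np.ndarray
    s: np.ndarray
    params: Parameters
    M: int
    m: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=int)
        self.s = np.asarray(self.s, dtype=float)
        if self.z.shape != (self.M,):
            raise ValueError("z must have length M")
        if self.s.shape != (self.M, 2):
            raise ValueError("s must have shape (M, 2)")
        if (self.z[: self.m] != 1).any():
            raise ValueError("marked individuals must have z = 1")

    @property
    def N(self) -> int:
        return int(self.z.sum())

    def copy(self) -> "AugmentedState":
        return AugmentedState(
            z=self.z.copy(),
            s=self.s.copy(),
            params=Parameters(*self.params.as_array()),
            M=self.M,
            m=self.m,
        )
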