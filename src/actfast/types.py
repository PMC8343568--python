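"""Core in-memory containers shared across the pipeline.

All matrices are plain numpy arrays; time (TR) is always axis 0 and
dimensions/voxels/actions are axis 1.  Action order is carried explicitly
as a list of string identifiers so that file round-trips are unambiguous.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The six action-space dimensions, in canonical column order.
DIMENSIONS: tuple[str, ...] = (
    "Abstraction",
    "Creation",
    "Tradition",
    "Food",
    "Animacy",
    "Spiritualism",
)


def zscore(x: np.ndarray, axis: int = 0, ddof: int = 1) -> np.ndarray:
    """Z-score along ``axis`` using the sample standard deviation.

    Columns with zero spread are centered but left unscaled (returned as
    zeros) rather than producing infinities.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=ddof, keepdims=True)
    out = x - mu
    safe = np.where(sd > 0, sd, 1.0)
    out = out / safe
    return out


@dataclass
class ActionCoordinates:
    """Per-action locations in the six-dimensional action space.

    ``coords`` is (n_actions, n_dims); rows follow ``action_ids``.  Rated
    and synthetic coordinates are z-scored per dimension across actions;
    decoded coordinates are whatever the decoder produced.
    """

    action_ids: list[str]
    coords: np.ndarray
    provenance: str = "synthetic"  # {"rated", "decoded", "synthetic"}
    dimensions: tuple[str, ...] = DIMENSIONS

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] != len(self.action_ids):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.action_ids)} action ids"
            )
        if self.provenance not in {"rated", "decoded", "synthetic"}:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_actions(self) -> int:
        return len(self.action_ids)

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    def index_of(self, action_id: str) -> int:
        return self.action_ids.index(action_id)


@dataclass
class AnnotationSeries:
    """Timepoint-by-action probability matrix (the soft on-screen labels)."""

    probs: np.ndarray  # (n_trs, n_actions), nonnegative
    action_ids: list[str]
    tr_length_s: float = 1.5

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(self.action_ids):
            raise ValueError("probs must be (n_trs, n_actions)")
        if np.any(self.probs < 0):
            raise ValueError("annotation probabilities must be nonnegative")
        if self.tr_length_s <= 0:
            raise ValueError("tr_length_s must be positive")

    @property
    def n_trs(self) -> int:
        return self.probs.shape[0]

    @property
    def n_actions(self) -> int:
        return self.probs.shape[1]


@dataclass
class DimensionTimeSeries:
    """Trajectory through the action space, one 6-vector per TR."""

    values: np.ndarray  # (n_trs, n_dims)
    tr_length_s: float = 1.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_trs, n_dims)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dimension time series must be finite")

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DiscreteAction:
    """A maximal run of TRs sharing the same most-probable action.

    Half-open interval [start_tr, end_tr) in 0-based TR indices.
    """

    action_id: str
    start_tr: int
    end_tr: int
    tr_length_s: float = 1.5

    def __post_init__(self) -> None:
        if self.end_tr <= self.start_tr:
            raise ValueError("end_tr must exceed start_tr")

    @property
    def n_trs(self) -> int:
        return self.end_tr - self.start_tr

    @property
    def duration_s(self) -> float:
        return self.n_trs * self.tr_length_s


@dataclass
class VoxelTimeSeries:
    """One participant's preprocessed BOLD matrix, z-scored per voxel."""

    participant_id: str
    data: np.ndarray  # (n_trs, n_voxels)
    tr_length_s: float = 1.5

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("voxel data must be 2-D (n_trs, n_voxels)")

    @property
    def n_trs(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class SyntheticWorld:
    """Ground truth for a simulated study.

    ``sequence`` is the planted ordered list of (action_id, duration_in_TRs)
    runs; consecutive entries always name distinct actions, so the runs are
    exactly the discrete actions recoverable from sharp annotations.
    """

    action_ids: list[str]
    true_coords: np.ndarray  # (n_actions, n_dims), z-scored per column
    sequence: list[tuple[str, int]]
    encoding_maps: list[np.ndarray] = field(default_factory=list)
    reliable_voxel_mask: np.ndarray | None = None
    seed: int = 0

    @property
    def n_trs(self) -> int:
        return sum(d for _, d in self.sequence)

    def coordinates(self) -> ActionCoordinates:
        return ActionCoordinates(
            list(self.action_ids), self.true_coords.copy(), provenance="synthetic"
        )
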