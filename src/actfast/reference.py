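"""Neurally-defined reference coordinates and cross-participant alignment.

Rated coordinates say where an action *should* sit in the space; the
decoder, being imperfect, places actions somewhere slightly different.
Because test-phase ranking consumes decoder output, the ranking anchors are
therefore *decoded* coordinates: the probability-weighted average of the
decoded training time series per action.  A Procrustes similarity
transform then maps the group-level reference configuration into each
participant's own decoded space — computed, like everything here, from
training data only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .types import AnnotationSeries, DimensionTimeSeries

__all__ = [
    "ReferenceCoordinates",
    "ProcrustesTransform",
    "compute_reference_coordinates",
    "procrustes_align",
]


@dataclass
class ReferenceCoordinates:
    """Decoded per-action anchor coordinates.

    ``mass`` is each action's total annotation probability over the
    training TRs; zero-mass actions carry NaN rows and are excluded from
    any candidate list (``valid`` is False there).
    """

    action_ids: list[str]
    coords: np.ndarray  # (n_actions, n_dims)
    mass: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.mass > 0

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


@dataclass
class ProcrustesTransform:
    """Similarity transform ``x -> scale * x @ rotation + translation``."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    residual: float  # sum of squared distances after alignment

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(x, float) @ self.rotation + self.translation


def compute_reference_coordinates(
    decoded: DimensionTimeSeries, series: AnnotationSeries
) -> ReferenceCoordinates:
    """Average decoded coordinates over time, weighted by each action's
    annotation probability: ``ref[a] = sum_t probs[t,a] * decoded[t] / mass[a]``."""
    if decoded.n_trs != series.n_trs:
        raise ValueError("decoded series and annotations must share TR counts")
    mass = series.probs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        coords = (series.probs.T @ decoded.values) / mass[:, None]
    coords[mass == 0] = np.nan
    return ReferenceCoordinates(list(series.action_ids), coords, mass)


def procrustes_align(
    group_ref: ReferenceCoordinates,
    participant_ref: ReferenceCoordinates,
    scaling: bool = True,
) -> tuple[ReferenceCoordinates, ProcrustesTransform]:
    """Least-squares similarity alignment of group onto participant space.

    Solves for orthogonal rotation, isotropic scale (optional) and
    translation minimizing ``||s * G @ R + t - P||_F^2`` over the actions
    valid in both configurations, then applies the transform to *all* group
    rows.  Requires at least ``n_dims + 1`` shared actions.
    """
    if group_ref.action_ids != participant_ref.action_ids:
        raise ValueError("reference configurations must share action order")
    shared = group_ref.valid & participant_ref.valid
    n_dims = group_ref.n_dims
    if int(shared.sum()) < n_dims + 1:
        raise ValueError(
            f"need at least {n_dims + 1} shared actions, got {int(shared.sum())}"
        )
    G = group_ref.coords[shared]
    P = participant_ref.coords[shared]
    mu_g = G.mean(axis=0)
    mu_p = P.mean(axis=0)
    A = G - mu_g
    B = P - mu_p
    R, trace = orthogonal_procrustes(A, B)
    denom = float((A * A).sum())
    if denom == 0:
        raise ValueError("group configuration is degenerate (zero spread)")
    s = float(trace) / denom if scaling else 1.0
    t = mu_p - s * mu_g @ R
    aligned_coords = s * group_ref.coords @ R + t
    residual = float(((s * G @ R + t - P) ** 2).sum())
    transform = ProcrustesTransform(rotation=R, scale=s, translation=t, residual=residual)
    aligned = ReferenceCoordinates(
        list(group_ref.action_ids), aligned_coords, group_ref.mass.copy()
    )
    return aligned, transform
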