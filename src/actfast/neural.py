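"""Voxel selection by cross-participant reliability and PLS decoding.

The decoding model maps multivoxel activity to coordinates on the six
action-space dimensions.  Training proceeds in two stages:

1. *Feature selection.*  For each voxel, compute its per-action response
   profile (probability-weighted average activity per action), measure the
   consistency of that profile across participants with Cronbach's alpha,
   and split voxels into action-sensitive / insensitive classes with a
   two-component Gaussian mixture on the alpha values.  The higher-mean
   component is the selected set.

2. *Decoding.*  Six independent partial least-squares regressions, one per
   dimension, from the selected voxels to the coordinate time series.  The
   single PLS hyperparameter — the number of latent components — is chosen
   per dimension by nested split-half cross-validation on the training TRs
   (contiguous temporal halves, scored by out-of-half Pearson correlation).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.mixture import GaussianMixture

from .types import DimensionTimeSeries

__all__ = [
    "action_pattern_matrix",
    "cronbach_alpha",
    "select_voxels",
    "fit_pls",
    "decode",
    "DecodingModel",
    "ReliabilityMap",
    "DegenerateMixtureError",
]


class DegenerateMixtureError(RuntimeError):
    """The two mixture components collapsed; fall back to a manual
    reliability threshold instead of the mixture split."""


def action_pattern_matrix(
    data: np.ndarray, probs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-action average activity pattern, weighted by annotation probability.

    ``pattern[a, v] = sum_t probs[t, a] * data[t, v] / sum_t probs[t, a]``.

    Returns ``(patterns, mass)`` where ``mass[a]`` is the total annotation
    probability of action ``a``; zero-mass actions get an all-NaN row
    (flagged, not fatal).
    """
    data = np.asarray(data, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if data.shape[0] != probs.shape[0]:
        raise ValueError("data and probs must have equal TR counts")
    mass = probs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        patterns = (probs.T @ data) / mass[:, None]
    patterns[mass == 0] = np.nan
    return patterns, mass


def cronbach_alpha(
    patterns: np.ndarray | list[np.ndarray], items: str = "participants"
) -> np.ndarray:
    """Cronbach's alpha of each voxel's per-action profile across participants.

    ``patterns`` stacks one action-by-voxel matrix per participant, shape
    (k participants, n actions, n voxels).  With ``items="participants"``
    (default) the k participants are the scale items and actions are the
    observations: ``alpha = k/(k-1) * (1 - sum_i var_i / var_total)`` where
    ``var_i`` is participant i's variance over actions and ``var_total`` the
    variance of the participant sum.  ``items="actions"`` swaps the roles.

    Actions with a missing (NaN) pattern in any participant are dropped.
    Voxels with zero total variance get NaN (undefined, flagged).
    """
    arr = np.asarray(patterns, dtype=float)
    if arr.ndim != 3:
        raise ValueError("patterns must stack to (participants, actions, voxels)")
    if items == "actions":
        arr = arr.transpose(1, 0, 2)
    elif items != "participants":
        raise ValueError("items must be 'participants' or 'actions'")
    k = arr.shape[0]
    if k < 2:
        raise ValueError("need at least 2 items for Cronbach's alpha")
    ok = ~np.isnan(arr).any(axis=(0, 2))
    arr = arr[:, ok, :]
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 complete observations")
    item_var = arr.var(axis=1, ddof=1)          # (k, voxels)
    total_var = arr.sum(axis=0).var(axis=0, ddof=1)  # (voxels,)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = k / (k - 1.0) * (1.0 - item_var.sum(axis=0) / total_var)
    alpha[total_var == 0] = np.nan
    return alpha


@dataclass
class ReliabilityMap:
    """Per-voxel reliability and the mixture-based selection that follows."""

    alpha: np.ndarray
    selected: np.ndarray  # boolean, True = action-sensitive
    means: np.ndarray     # two component means, index 0 = lower
    variances: np.ndarray
    weights: np.ndarray

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def select_voxels(alphas: np.ndarray, seed: int = 0) -> ReliabilityMap:
    """Two-component 1-D Gaussian mixture split of the voxel reliabilities.

    Fit by EM (k-means initialization, tolerance 1e-6, up to 500
    iterations) on the sorted finite alphas, so the result is invariant to
    voxel order; voxels are assigned by posterior argmax and the
    higher-mean component is 'selected'.  Non-finite alphas are never
    selected.  Raises ``DegenerateMixtureError`` when the components
    collapse.
    """
    alphas = np.asarray(alphas, dtype=float)
    finite = np.isfinite(alphas)
    x = alphas[finite]
    if x.size < 2:
        raise ValueError("need at least 2 finite reliability values")
    spread = float(np.ptp(x))
    if spread == 0.0:
        raise DegenerateMixtureError(
            "all reliabilities equal; apply a manual threshold instead"
        )
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        tol=1e-6,
        max_iter=500,
        n_init=1,
        init_params="kmeans",
        random_state=seed,
    ).fit(np.sort(x).reshape(-1, 1))
    means = gm.means_.ravel()
    if abs(means[0] - means[1]) <= 1e-6 * spread:
        raise DegenerateMixtureError(
            "mixture components collapsed; apply a manual threshold instead"
        )
    order = np.argsort(means)
    high = int(order[1])
    post = gm.predict_proba(x.reshape(-1, 1))
    selected = np.zeros_like(finite)
    selected[finite] = post.argmax(axis=1) == high
    return ReliabilityMap(
        alpha=alphas,
        selected=selected,
        means=means[order],
        variances=gm.covariances_.ravel()[order],
        weights=gm.weights_.ravel()[order],
    )


@dataclass
class DecodingModel:
    """Six fitted voxel-to-dimension regressions.

    ``coefs`` is (n_dims, n_voxels); prediction for dimension d is
    ``X @ coefs[d] + intercepts[d]``.  ``n_components[d]`` records the
    component count chosen by the nested split-half procedure.
    """

    coefs: np.ndarray
    intercepts: np.ndarray
    n_components: np.ndarray
    max_components: int
    cv_scores: np.ndarray = field(default=None)  # (n_dims, max_components)
    tr_length_s: float = 1.5

    @property
    def n_dims(self) -> int:
        return self.coefs.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.coefs.shape[1]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def _fit_single(X: np.ndarray, y: np.ndarray, c: int) -> tuple[np.ndarray, float]:
    pls = PLSRegression(n_components=c, scale=False)
    pls.fit(X, y)
    coef = pls.coef_.ravel().copy()
    # sklearn predicts on centered features; fold the centering into the
    # intercept so predictions are a plain affine map of X
    intercept = float(np.ravel(pls.intercept_)[0] - pls._x_mean @ coef)
    return coef, intercept


def fit_pls(
    features: np.ndarray,
    targets: DimensionTimeSeries | np.ndarray,
    max_components: int = 20,
    seed: int = 0,
) -> DecodingModel:
    """Fit one PLS regression per dimension with nested split-half model
    selection.

    The training TRs are split into two contiguous halves; for each
    candidate component count the model is fit on each half and scored by
    the Pearson correlation of its predictions on the other half (averaged
    over the two directions).  The best count (ties to the smaller) is then
    refit on all training TRs.  ``seed`` is accepted for interface symmetry;
    the procedure is deterministic.
    """
    X = np.asarray(features, dtype=float)
    Y = targets.values if isinstance(targets, DimensionTimeSeries) else np.asarray(targets, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("features and targets must have equal TR counts")
    n, _ = X.shape
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    if n < 2 * max_components:
        raise ValueError(
            f"need at least 2*max_components={2 * max_components} TRs, got {n}"
        )
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if max_components > rank:
        raise ValueError(
            f"max_components={max_components} exceeds feature rank {rank}"
        )
    half = n // 2
    A, B = slice(0, half), slice(half, n)
    n_dims = Y.shape[1]
    scores = np.full((n_dims, max_components), -np.inf)
    chosen = np.zeros(n_dims, dtype=int)
    coefs = np.zeros((n_dims, X.shape[1]))
    intercepts = np.zeros(n_dims)
    for d in range(n_dims):
        y = Y[:, d]
        for ci in range(max_components):
            c = ci + 1
            wa, ba = _fit_single(X[A], y[A], c)
            wb, bb = _fit_single(X[B], y[B], c)
            r1 = _pearson(X[B] @ wa + ba, y[B])
            r2 = _pearson(X[A] @ wb + bb, y[A])
            if np.isnan(r1) or np.isnan(r2):
                continue
            scores[d, ci] = 0.5 * (r1 + r2)
        best = int(np.argmax(scores[d]))  # argmax takes the first (smallest c) tie
        chosen[d] = best + 1
        coefs[d], intercepts[d] = _fit_single(X, y, chosen[d])
    tr = targets.tr_length_s if isinstance(targets, DimensionTimeSeries) else 1.5
    return DecodingModel(
        coefs=coefs,
        intercepts=intercepts,
        n_components=chosen,
        max_components=max_components,
        cv_scores=scores,
        tr_length_s=tr,
    )


def decode(model: DecodingModel, features: np.ndarray) -> DimensionTimeSeries:
    """Apply the fitted regressions: linear map of voxel patterns to the
    six-dimensional coordinate series."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_voxels:
        raise ValueError(
            f"feature columns {X.shape[1] if X.ndim == 2 else X.shape} do not "
            f"match the model's {model.n_voxels} selected voxels"
        )
    return DimensionTimeSeries(X @ model.coefs.T + model.intercepts, model.tr_length_s)
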