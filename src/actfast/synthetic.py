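"""Synthetic study generator with planted ground truth.

Every downstream stage of the pipeline (rating aggregation, decoding,
reference alignment, proximity prediction) can be exercised against a world
whose action coordinates, action sequence, annotation noise and voxel
encoding are all known exactly.

The generative model, in brief:

* actions live at z-scored Gaussian coordinates in a 6-D space;
* the action sequence is a Markov chain whose transition probabilities are
  a softmax of negative Euclidean distance, ``P(j | i) ∝ exp(-d(i, j)/τ)``
  for ``j ≠ i`` — nearby actions follow each other;
* soft annotations put a fixed probability mass on the true action per TR
  and scatter the remainder;
* each participant's reliable voxels are a shared linear image of the
  coordinate trajectory, seen through a small participant-specific rotation
  of the space, plus Gaussian noise; unreliable voxels are unit-variance
  noise.  Every voxel is z-scored over time, mirroring standard fMRI
  preprocessing.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.spatial.distance import cdist

from .types import (
    DIMENSIONS,
    ActionCoordinates,
    AnnotationSeries,
    DimensionTimeSeries,
    SyntheticWorld,
    VoxelTimeSeries,
    zscore,
)

__all__ = [
    "generate_action_space",
    "generate_action_sequence",
    "generate_annotations",
    "generate_voxel_data",
    "generate_ratings",
    "build_world",
]


def generate_action_space(
    n_actions: int, n_dims: int = 6, seed: int = 0
) -> ActionCoordinates:
    """Draw ``n_actions`` independent Gaussian points, z-scored per dimension.

    Requires ``n_actions >= n_dims + 1`` so the configuration spans the
    space (and downstream Procrustes fits are determined).
    """
    if n_actions < 2:
        raise ValueError("need at least 2 actions for a non-degenerate space")
    if n_actions < n_dims + 1:
        raise ValueError(
            f"n_actions={n_actions} must be at least n_dims+1={n_dims + 1}"
        )
    rng = np.random.default_rng(seed)
    coords = zscore(rng.standard_normal((n_actions, n_dims)))
    width = max(3, len(str(n_actions - 1)))
    ids = [f"action_{i:0{width}d}" for i in range(n_actions)]
    dims = DIMENSIONS if n_dims == 6 else tuple(f"dim_{i + 1}" for i in range(n_dims))
    return ActionCoordinates(ids, coords, provenance="synthetic", dimensions=dims)


def _transition_matrix(coords: np.ndarray, temperature: float) -> np.ndarray:
    """Row-stochastic softmax-of-negative-distance transitions, zero diagonal."""
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    # subtract the row-min before exponentiating so tiny temperatures do not
    # underflow to an all-zero row
    dmin = d.min(axis=1, keepdims=True)
    if math.isinf(temperature):
        w = np.ones_like(d)
        np.fill_diagonal(w, 0.0)
    else:
        w = np.exp(-(d - dmin) / temperature)
        w[~np.isfinite(w)] = 0.0
    return w / w.sum(axis=1, keepdims=True)


def generate_action_sequence(
    coords: ActionCoordinates,
    n_steps: int,
    temperature: float,
    seed: int = 0,
) -> list[str]:
    """Sample a proximity-structured action chain.

    The first action is uniform; each subsequent action ``j`` follows the
    current ``i`` with probability proportional to ``exp(-d(i, j)/temperature)``
    over ``j != i``.  ``temperature=math.inf`` gives uniform transitions
    (the negative-control regime).
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be positive")
    rng = np.random.default_rng(seed)
    P = _transition_matrix(coords.coords, temperature)
    cum = np.cumsum(P, axis=1)
    n = coords.n_actions
    seq = np.empty(n_steps, dtype=int)
    seq[0] = rng.integers(n)
    u = rng.random(n_steps)
    for t in range(1, n_steps):
        seq[t] = np.searchsorted(cum[seq[t - 1]], u[t], side="right")
    return [coords.action_ids[i] for i in seq]


def generate_annotations(
    sequence: list[tuple[str, int]],
    action_ids: list[str],
    concentration: float,
    seed: int = 0,
    tr_length_s: float = 1.5,
) -> AnnotationSeries:
    """Soft labels: the on-screen action gets ``concentration`` of each row.

    The remaining ``1 - concentration`` is spread over the other actions
    with random nonnegative weights; every row sums to one.  At
    ``concentration=1`` rows are one-hot.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if not 0 < concentration <= 1:
        raise ValueError("concentration must lie in (0, 1]")
    index = {a: i for i, a in enumerate(action_ids)}
    rng = np.random.default_rng(seed)
    n_trs = sum(d for _, d in sequence)
    n_actions = len(action_ids)
    probs = np.zeros((n_trs, n_actions))
    t = 0
    for action, dur in sequence:
        if dur < 1:
            raise ValueError("durations must be >= 1 TR")
        try:
            a = index[action]
        except KeyError:
            raise ValueError(f"sequence action {action!r} not in action_ids") from None
        for _ in range(dur):
            row = np.zeros(n_actions)
            if concentration < 1 and n_actions > 1:
                bg = rng.random(n_actions)
                bg[a] = 0.0
                row = (1.0 - concentration) * bg / bg.sum()
            row[a] += concentration
            probs[t] = row
            t += 1
    return AnnotationSeries(probs, list(action_ids), tr_length_s=tr_length_s)


def _small_rotation(n_dims: int, angle_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Random orthogonal matrix near the identity (matrix exponential of a
    small skew-symmetric matrix)."""
    a = rng.standard_normal((n_dims, n_dims)) * angle_sd
    return expm(a - a.T)


def generate_voxel_data(
    dim_series: DimensionTimeSeries,
    n_participants: int,
    n_voxels: int,
    n_reliable: int,
    noise_sd: float,
    seed: int = 0,
    rotation_sd: float = 0.1,
) -> tuple[list[VoxelTimeSeries], dict]:
    """Simulate multi-participant BOLD encoding the coordinate trajectory.

    Reliable voxels carry ``(dim_series @ R_p) @ W`` where ``W`` is a shared
    6-by-voxel map and ``R_p`` a small participant-specific rotation (so
    that cross-participant alignment has a true solution), plus Gaussian
    noise of ``noise_sd``.  Unreliable voxels are independent unit-variance
    noise regardless of ``noise_sd``.  Each voxel is z-scored over time.

    Returns the per-participant series and a bookkeeping dict with
    ``reliable_mask`` (boolean per voxel), ``shared_map`` and per-participant
    ``rotations``.
    """
    if not 0 < n_reliable <= n_voxels:
        raise ValueError("need 0 < n_reliable <= n_voxels")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    n_trs, n_dims = dim_series.values.shape
    shared_map = rng.standard_normal((n_dims, n_reliable))
    order = rng.permutation(n_voxels)
    reliable_mask = np.zeros(n_voxels, dtype=bool)
    reliable_mask[order[:n_reliable]] = True

    out: list[VoxelTimeSeries] = []
    rotations: list[np.ndarray] = []
    for p in range(n_participants):
        R = _small_rotation(n_dims, rotation_sd, rng)
        rotations.append(R)
        data = np.empty((n_trs, n_voxels))
        signal = (dim_series.values @ R) @ shared_map
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
        data[:, reliable_mask] = signal
        data[:, ~reliable_mask] = rng.standard_normal((n_trs, n_voxels - n_reliable))
        out.append(
            VoxelTimeSeries(
                participant_id=f"sub-{p + 1:02d}",
                data=zscore(data),
                tr_length_s=dim_series.tr_length_s,
            )
        )
    info = {
        "reliable_mask": reliable_mask,
        "shared_map": shared_map,
        "rotations": rotations,
    }
    return out, info


def generate_ratings(
    coords: ActionCoordinates,
    n_raters_per_dim: int,
    rater_noise_sd: float,
    n_degenerate: int = 0,
    seed: int = 0,
    actions_per_rater: int = 70,
    bias_sd: float = 0.5,
    discretize: bool = True,
) -> pd.DataFrame:
    """Simulate a per-rater rating table over the true coordinates.

    Each rater is assigned to a single dimension and rates a subset of
    actions (``actions_per_rater``, covering all actions round-robin so no
    (action, dimension) cell is left empty).  A rating is the true
    coordinate plus a rater-specific additive bias and Gaussian noise,
    mapped onto a bounded 1-100 integer scale when ``discretize`` is set.

    ``n_degenerate`` extra raters answer from a palette of five fixed values
    so the downstream low-variability exclusion rule has planted targets.
    """
    if n_raters_per_dim < 2:
        raise ValueError("need at least 2 raters per dimension")
    rng = np.random.default_rng(seed)
    n_actions = coords.n_actions
    per = min(actions_per_rater, n_actions)
    rows: list[tuple[str, str, str, float]] = []
    rater_no = 0
    for d, dim in enumerate(coords.dimensions):
        # shuffled round-robin assignment: chunk a stream of permutations so
        # coverage of every action is guaranteed once n_raters*per >= n_actions
        stream: list[int] = []
        while len(stream) < n_raters_per_dim * per:
            stream.extend(rng.permutation(n_actions).tolist())
        for r in range(n_raters_per_dim):
            rater = f"rater_{rater_no:04d}"
            rater_no += 1
            bias = rng.normal(0.0, bias_sd) if bias_sd > 0 else 0.0
            items = stream[r * per : (r + 1) * per]
            for a in items:
                val = coords.coords[a, d] + bias
                if rater_noise_sd > 0:
                    val += rng.normal(0.0, rater_noise_sd)
                if discretize:
                    val = float(np.clip(round(50.5 + 16.0 * val), 1, 100))
                rows.append((rater, coords.action_ids[a], dim, float(val)))
    for g in range(n_degenerate):
        rater = f"rater_{rater_no:04d}"
        rater_no += 1
        dim = coords.dimensions[g % len(coords.dimensions)]
        palette = rng.choice(np.arange(1, 101), size=5, replace=False)
        items = rng.choice(n_actions, size=per, replace=False)
        for a in items:
            rows.append(
                (rater, coords.action_ids[a], dim, float(rng.choice(palette)))
            )
    return pd.DataFrame(rows, columns=["rater_id", "action_id", "dimension", "rating"])


def build_world(
    n_actions: int = 332,
    n_dims: int = 6,
    n_trs: int = 2000,
    n_participants: int = 4,
    n_voxels: int = 200,
    n_reliable: int = 100,
    temperature: float = 0.3,
    concentration: float = 0.6,
    noise_sd: float = 0.3,
    mean_duration_trs: float = 3.0,
    tr_length_s: float = 1.5,
    seed: int = 0,
) -> tuple[SyntheticWorld, AnnotationSeries, list[VoxelTimeSeries]]:
    """Assemble a full synthetic study: coordinates, sequence, annotations
    and voxel data, all traceable to one seed.

    Run durations are ``2 + Poisson(mean_duration_trs - 2)`` TRs, matching
    naturalistic discrete-action lengths of a few seconds at a 1.5 s TR.
    ``temperature=math.inf`` yields uniformly random transitions.
    """
    if mean_duration_trs < 2:
        raise ValueError("mean_duration_trs must be >= 2")
    root = np.random.SeedSequence(seed)
    s_space, s_seq, s_dur, s_ann, s_vox = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(5)
    )
    coords = generate_action_space(n_actions, n_dims, seed=s_space)
    # oversample steps, then trim runs to exactly n_trs
    approx_steps = max(4, int(math.ceil(n_trs / 2.0)))
    actions = generate_action_sequence(coords, approx_steps, temperature, seed=s_seq)
    dur_rng = np.random.default_rng(s_dur)
    sequence: list[tuple[str, int]] = []
    total = 0
    for a in actions:
        d = int(2 + dur_rng.poisson(mean_duration_trs - 2.0))
        if total + d >= n_trs:
            sequence.append((a, n_trs - total))
            total = n_trs
            break
        sequence.append((a, d))
        total += d
    if total < n_trs:
        raise RuntimeError("internal: sequence did not cover requested TRs")

    annotations = generate_annotations(
        sequence, coords.action_ids, concentration, seed=s_ann, tr_length_s=tr_length_s
    )
    # the neural signal encodes the coordinates of the action truly on screen
    idx = {a: i for i, a in enumerate(coords.action_ids)}
    tr_action = np.repeat(
        [idx[a] for a, _ in sequence], [d for _, d in sequence]
    )
    dim_series = DimensionTimeSeries(coords.coords[tr_action], tr_length_s=tr_length_s)
    voxels, info = generate_voxel_data(
        dim_series, n_participants, n_voxels, n_reliable, noise_sd, seed=s_vox
    )
    world = SyntheticWorld(
        action_ids=list(coords.action_ids),
        true_coords=coords.coords,
        sequence=sequence,
        encoding_maps=[info["shared_map"]] + info["rotations"],
        reliable_voxel_mask=info["reliable_mask"],
        seed=seed,
    )
    return world, annotations, voxels
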