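"""Proximity-based action identification and prediction.

At test time each discrete action's decoded coordinates are compared, by
Euclidean distance, against the reference coordinates of every candidate
action, yielding a full ranking from nearest to farthest.  Top-k accuracy
is scored at lags 0..max_lag: the lag-0 ranking of run *i* is asked whether
it contains the true action of run *i + L* — future runs are never decoded.
Significance comes from a permutation null that reassigns which action owns
which reference row.

``bi_cross_validate`` wraps the whole chain in the bi-cross-validation
scheme: every (held-out video section, held-out participant) pair is one
fold; feature selection, PLS training, reference computation and Procrustes
alignment see training data only.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .annotations import coordinate_time_series, segment_discrete_actions
from .neural import (
    DecodingModel,
    action_pattern_matrix,
    cronbach_alpha,
    decode,
    fit_pls,
    select_voxels,
)
from .reference import (
    ReferenceCoordinates,
    ProcrustesTransform,
    compute_reference_coordinates,
    procrustes_align,
)
from .types import (
    ActionCoordinates,
    AnnotationSeries,
    DimensionTimeSeries,
    DiscreteAction,
    VoxelTimeSeries,
)

__all__ = [
    "RankedPrediction",
    "LagAccuracyResult",
    "FoldModel",
    "FoldResult",
    "BiCVResult",
    "decode_discrete_action",
    "rank_candidates",
    "topk_accuracy_at_lags",
    "null_permutation_hits",
    "permutation_pvalues",
    "section_slices",
    "train_fold",
    "evaluate_fold",
    "bi_cross_validate",
]


# ---------------------------------------------------------------------------
# single-run primitives


def decode_discrete_action(
    decoded: DimensionTimeSeries, run: DiscreteAction
) -> np.ndarray:
    """Unweighted mean of the decoded rows inside the run's TR interval."""
    if run.start_tr < 0 or run.end_tr > decoded.n_trs:
        raise ValueError("run lies outside the decoded segment")
    return decoded.values[run.start_tr : run.end_tr].mean(axis=0)


@dataclass
class RankedPrediction:
    """Full candidate ranking for one discrete action, nearest first."""

    decoded_coords: np.ndarray
    ranking: np.ndarray    # candidate indices, nearest first
    distances: np.ndarray  # distances in ranking order (non-decreasing)


def rank_candidates(
    point: np.ndarray,
    reference: np.ndarray,
    dims: np.ndarray | list[int] | None = None,
) -> RankedPrediction:
    """Rank candidates by Euclidean distance to ``point``.

    ``reference`` is (n_candidates, n_dims); ``dims`` optionally restricts
    the distance to a subset of dimensions (single-dimension rankings use a
    one-element subset).  Ties are broken by candidate index (stable sort).
    """
    point = np.asarray(point, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("empty candidate reference")
    if dims is not None:
        dims = np.asarray(dims, dtype=int)
        if dims.size == 0:
            raise ValueError("dims subset must be non-empty")
        ref = ref[:, dims]
        point = point[dims]
    d = np.sqrt(((ref - point) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")
    return RankedPrediction(
        decoded_coords=point, ranking=order, distances=d[order]
    )


def topk_accuracy_at_lags(
    topk: np.ndarray,
    run_actions: np.ndarray,
    k: int,
    max_lag: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Top-k hit rate at lags 0..max_lag.

    ``topk`` is (n_runs, k): the k nearest candidate indices from each
    run's lag-0 ranking.  ``run_actions`` gives each run's true candidate
    index (-1 when the true action is not in the candidate set, which can
    never be a hit).  Run *i* at lag *L* is a hit when
    ``run_actions[i + L]`` appears in ``topk[i]``; instances running past
    the end of the segment are skipped.  A lag with zero instances raises.
    """
    topk = np.asarray(topk)
    run_actions = np.asarray(run_actions)
    n = run_actions.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if topk.shape[0] != n:
        raise ValueError("topk and run_actions must align")
    acc = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    for L in range(max_lag + 1):
        m = n - L
        if m <= 0:
            raise ValueError(f"lag {L} has zero instances ({n} runs)")
        hits = (topk[:m] == run_actions[L : L + m, None]).any(axis=1)
        acc[L] = hits.mean()
        counts[L] = m
    return acc, counts


# ---------------------------------------------------------------------------
# permutation machinery


def null_permutation_hits(
    topk: np.ndarray,
    run_actions: np.ndarray,
    permutations: np.ndarray,
    max_lag: int,
) -> np.ndarray:
    """Per-permutation lag accuracies under relabelled reference ownership.

    A permutation ``sigma`` makes candidate ``a`` take over the reference
    coordinates of ``sigma[a]``; distances are unchanged, so the permuted
    top-k set of a run is the preimage of the observed one, and run *i* at
    lag *L* is a hit iff ``sigma[run_actions[i+L]]`` is in ``topk[i]``.
    Returns (n_permutations, max_lag+1) accuracies.
    """
    perms = np.asarray(permutations)
    n = run_actions.shape[0]
    out = np.zeros((perms.shape[0], max_lag + 1))
    for L in range(max_lag + 1):
        m = n - L
        future = run_actions[L : L + m]
        ok = future >= 0
        mapped = perms[:, future[ok]]                      # (P, m_ok)
        hits = (topk[:m][ok][None, :, :] == mapped[:, :, None]).any(axis=2)
        total = hits.sum(axis=1)
        out[:, L] = total / m
    return out


def permutation_pvalues(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """One-tailed permutation p-values with the +1 correction."""
    observed = np.asarray(observed)
    null = np.asarray(null)
    n_perm = null.shape[0]
    ge = (null >= observed[None, :]).sum(axis=0)
    return (1.0 + ge) / (1.0 + n_perm)


# ---------------------------------------------------------------------------
# bi-cross-validation


def section_slices(n_trs: int, n_sections: int) -> list[slice]:
    """Contiguous, approximately equal sections tiling [0, n_trs)."""
    if n_sections < 2:
        raise ValueError("need at least 2 sections")
    if n_trs < n_sections:
        raise ValueError("fewer TRs than sections")
    edges = np.linspace(0, n_trs, n_sections + 1).round().astype(int)
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class FoldModel:
    """Everything trained within one fold (training data only)."""

    test_section: int
    test_participant: str
    selected: np.ndarray
    model: DecodingModel
    group_ref: ReferenceCoordinates
    aligned_ref: ReferenceCoordinates
    transform: ProcrustesTransform
    candidates: np.ndarray  # candidate action indices into the full action list
    alpha: np.ndarray

    def content_hash(self) -> str:
        """Digest of all trained content — must be blind to test data."""
        h = hashlib.sha256()
        for arr in (
            self.selected.astype(np.uint8),
            np.round(self.model.coefs, 10),
            np.round(self.model.intercepts, 10),
            self.model.n_components,
            np.round(self.group_ref.coords[self.group_ref.valid], 10),
            np.round(self.aligned_ref.coords[self.aligned_ref.valid], 10),
            np.round(self.transform.rotation, 10),
            np.round(np.atleast_1d(self.transform.scale), 10),
            np.round(self.transform.translation, 10),
            self.candidates,
        ):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


@dataclass
class FoldResult:
    test_section: int
    test_participant: str
    observed: np.ndarray       # (max_lag+1,)
    counts: np.ndarray
    null: np.ndarray           # (n_permutations, max_lag+1)
    p_values: np.ndarray
    n_runs: int
    model_hash: str


@dataclass
class LagAccuracyResult:
    """Pooled accuracy per lag with its permutation null."""

    k: int
    max_lag: int
    observed_accuracy: np.ndarray          # (max_lag+1,) mean over folds
    null_distribution: np.ndarray          # (n_permutations, max_lag+1)
    p_values: np.ndarray                   # group-level, per lag
    n_instances: np.ndarray                # summed over folds


@dataclass
class BiCVResult:
    folds: list[FoldResult]
    pooled: LagAccuracyResult
    participant_p: dict[str, np.ndarray]
    fraction_participants_significant: np.ndarray  # per lag, at p < 0.05
    n_candidates: int
    config: dict = field(default_factory=dict)


def train_fold(
    annotations: AnnotationSeries,
    coords: ActionCoordinates,
    voxel_data: list[VoxelTimeSeries],
    test_section: int,
    test_participant: str,
    sections: list[slice],
    max_components: int = 20,
    alpha_items: str = "participants",
    procrustes_scaling: bool = True,
    seed: int = 0,
) -> FoldModel:
    """Train every component of the pipeline on training data only.

    Training data = all sections except ``test_section`` from all
    participants except ``test_participant``.  The held-out participant's
    *training-section* TRs are used once, at the end, as the Procrustes
    target defining that participant's own representational space.
    """
    train_trs = np.concatenate(
        [np.arange(s.start, s.stop) for i, s in enumerate(sections) if i != test_section]
    )
    train_parts = [v for v in voxel_data if v.participant_id != test_participant]
    if not train_parts:
        raise ValueError("no training participants left")
    test_vox = next(
        (v for v in voxel_data if v.participant_id == test_participant), None
    )
    if test_vox is None:
        raise ValueError(f"unknown participant {test_participant!r}")

    probs_train = annotations.probs[train_trs]
    ann_train = AnnotationSeries(
        probs_train, list(annotations.action_ids), annotations.tr_length_s
    )

    # 1) reliability-based feature selection across training participants
    patterns = np.stack(
        [action_pattern_matrix(v.data[train_trs], probs_train)[0] for v in train_parts]
    )
    alpha = cronbach_alpha(patterns, items=alpha_items)
    relmap = select_voxels(alpha, seed=seed)
    sel = relmap.selected

    # 2) six PLS decoders on stacked training participants
    dim_series = coordinate_time_series(ann_train, coords)
    X = np.vstack([v.data[train_trs][:, sel] for v in train_parts])
    Y = np.tile(dim_series.values, (len(train_parts), 1))
    # clamp the component search to what the selected features can support
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    model = fit_pls(X, Y, max_components=min(max_components, rank), seed=seed)

    # 3) group reference coordinates from decoded training TRs
    probs_stacked = np.tile(probs_train, (len(train_parts), 1))
    ann_stacked = AnnotationSeries(
        probs_stacked, list(annotations.action_ids), annotations.tr_length_s
    )
    group_ref = compute_reference_coordinates(decode(model, X), ann_stacked)

    # 4) participant's own space: decode their training TRs, align group onto it
    part_decoded = decode(model, test_vox.data[train_trs][:, sel])
    part_ref = compute_reference_coordinates(part_decoded, ann_train)
    aligned_ref, transform = procrustes_align(
        group_ref, part_ref, scaling=procrustes_scaling
    )

    candidates = np.nonzero(group_ref.valid & part_ref.valid)[0]
    if candidates.size == 0:
        raise ValueError("training fold leaves an empty candidate set")
    return FoldModel(
        test_section=test_section,
        test_participant=test_participant,
        selected=sel,
        model=model,
        group_ref=group_ref,
        aligned_ref=aligned_ref,
        transform=transform,
        candidates=candidates,
        alpha=alpha,
    )


def evaluate_fold(
    fold: FoldModel,
    annotations: AnnotationSeries,
    voxel_data: list[VoxelTimeSeries],
    sections: list[slice],
    k: int = 5,
    max_lag: int = 5,
    dims: np.ndarray | list[int] | None = None,
    permutations: np.ndarray | None = None,
) -> FoldResult:
    """Score the held-out (section, participant) pair.

    Discrete actions are segmented within the test section only; each run's
    decoded mean is ranked against the participant-aligned reference
    coordinates of the fold's candidate actions.
    """
    sec = sections[fold.test_section]
    test_vox = next(
        v for v in voxel_data if v.participant_id == fold.test_participant
    )
    ann_test = AnnotationSeries(
        annotations.probs[sec], list(annotations.action_ids), annotations.tr_length_s
    )
    runs = segment_discrete_actions(ann_test)
    decoded = decode(fold.model, test_vox.data[sec][:, fold.selected])

    ref = fold.aligned_ref.coords[fold.candidates]
    cand_index = {int(a): j for j, a in enumerate(fold.candidates)}
    action_pos = {a: i for i, a in enumerate(annotations.action_ids)}

    n_runs = len(runs)
    kk = min(k, len(fold.candidates))
    topk = np.zeros((n_runs, kk), dtype=int)
    run_actions = np.zeros(n_runs, dtype=int)
    for i, run in enumerate(runs):
        point = decode_discrete_action(decoded, run)
        ranked = rank_candidates(point, ref, dims=dims)
        topk[i] = ranked.ranking[:kk]
        run_actions[i] = cand_index.get(action_pos[run.action_id], -1)

    observed, counts = topk_accuracy_at_lags(topk, run_actions, kk, max_lag)
    if permutations is None:
        null = np.zeros((0, max_lag + 1))
        p = np.full(max_lag + 1, np.nan)
    else:
        null = null_permutation_hits(topk, run_actions, permutations, max_lag)
        p = permutation_pvalues(observed, null)
    return FoldResult(
        test_section=fold.test_section,
        test_participant=fold.test_participant,
        observed=observed,
        counts=counts,
        null=null,
        p_values=p,
        n_runs=n_runs,
        model_hash=fold.content_hash(),
    )


def bi_cross_validate(
    annotations: AnnotationSeries,
    coords: ActionCoordinates,
    voxel_data: list[VoxelTimeSeries],
    n_sections: int = 5,
    k: int = 5,
    max_lag: int = 5,
    max_components: int = 20,
    n_permutations: int = 1000,
    dims: np.ndarray | list[int] | None = None,
    alpha_items: str = "participants",
    procrustes_scaling: bool = True,
    seed: int = 0,
    folds: list[tuple[int, str]] | None = None,
) -> BiCVResult:
    """Run the full pipeline over every (section, participant) fold.

    Permutations are shared across folds (generated once from ``seed``), so
    per-permutation fold means are comparable and the group-level null is
    the distribution of across-fold mean accuracies.  ``folds`` optionally
    subsamples the fold grid.
    """
    if len(voxel_data) < 3:
        raise ValueError(
            "need at least 3 participants: each training fold must retain "
            ">= 2 for the cross-participant reliability step"
        )
    n_trs = annotations.n_trs
    if any(v.n_trs != n_trs for v in voxel_data):
        raise ValueError("participants and annotations disagree on TR count")
    sections = section_slices(n_trs, n_sections)
    participants = [v.participant_id for v in voxel_data]
    if folds is None:
        folds = [(s, p) for s in range(n_sections) for p in participants]

    rng = np.random.default_rng(seed)
    n_actions = annotations.n_actions

    fold_results: list[FoldResult] = []
    perms_by_size: dict[int, np.ndarray] = {}
    for s, p in folds:
        fm = train_fold(
            annotations,
            coords,
            voxel_data,
            test_section=s,
            test_participant=p,
            sections=sections,
            max_components=max_components,
            alpha_items=alpha_items,
            procrustes_scaling=procrustes_scaling,
            seed=seed,
        )
        ncand = len(fm.candidates)
        if ncand not in perms_by_size:
            # one shared permutation set per candidate-set size, drawn from a
            # fold-independent stream so every fold sees the same relabelings
            prng = np.random.default_rng(np.random.SeedSequence([seed, ncand]))
            perms_by_size[ncand] = np.stack(
                [prng.permutation(ncand) for _ in range(n_permutations)]
            )
        fr = evaluate_fold(
            fm,
            annotations,
            voxel_data,
            sections,
            k=k,
            max_lag=max_lag,
            dims=dims,
            permutations=perms_by_size[ncand],
        )
        fold_results.append(fr)

    observed = np.mean([f.observed for f in fold_results], axis=0)
    null = np.mean([f.null for f in fold_results], axis=0)
    group_p = permutation_pvalues(observed, null)
    counts = np.sum([f.counts for f in fold_results], axis=0)

    participant_p: dict[str, np.ndarray] = {}
    for p in participants:
        mine = [f for f in fold_results if f.test_participant == p]
        if not mine:
            continue
        obs_p = np.mean([f.observed for f in mine], axis=0)
        null_p = np.mean([f.null for f in mine], axis=0)
        participant_p[p] = permutation_pvalues(obs_p, null_p)
    frac_sig = np.mean(
        [pv < 0.05 for pv in participant_p.values()], axis=0
    )

    pooled = LagAccuracyResult(
        k=k,
        max_lag=max_lag,
        observed_accuracy=observed,
        null_distribution=null,
        p_values=group_p,
        n_instances=counts,
    )
    return BiCVResult(
        folds=fold_results,
        pooled=pooled,
        participant_p=participant_p,
        fraction_participants_significant=frac_sig,
        n_candidates=max(perms_by_size) if perms_by_size else 0,
        config={
            "n_sections": n_sections,
            "k": k,
            "max_lag": max_lag,
            "max_components": max_components,
            "n_permutations": n_permutations,
            "alpha_items": alpha_items,
            "procrustes_scaling": procrustes_scaling,
            "seed": seed,
            "n_folds": len(fold_results),
            "dims": None if dims is None else list(map(int, np.asarray(dims))),
        },
    )
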