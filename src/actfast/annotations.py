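"""Operations on the timepoint-by-action probability matrix.

Covers variant merging (e.g. collapsing agent-specific labels like
"male_singing"/"female_singing" into one "singing" column), construction of
the 6-D coordinate time series by probability-weighted averaging of action
coordinates, hemodynamic lag alignment by a whole-TR shift, and
segmentation of the series into discrete actions (maximal runs of the
per-TR most-probable action).
"""
from __future__ import annotations

import numpy as np

from .types import ActionCoordinates, AnnotationSeries, DimensionTimeSeries, DiscreteAction

__all__ = [
    "merge_action_variants",
    "coordinate_time_series",
    "shift_for_hemodynamics",
    "segment_discrete_actions",
    "repeat_to_tr_resolution",
]


def merge_action_variants(
    series: AnnotationSeries, merge_map: dict[str, str]
) -> AnnotationSeries:
    """Collapse variant columns into canonical ones by per-TR averaging.

    ``merge_map`` maps variant ids to canonical ids.  Canonical ids may be
    new or may coincide with an existing (unmerged) column, in which case
    that column joins its group.  Unmapped columns pass through untouched.
    """
    unknown = [v for v in merge_map if v not in series.action_ids]
    if unknown:
        raise ValueError(f"merge_map names unknown action ids: {unknown}")
    if not merge_map:
        return AnnotationSeries(
            series.probs.copy(), list(series.action_ids), series.tr_length_s
        )
    canonical = {a: merge_map.get(a, a) for a in series.action_ids}
    out_ids: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, a in enumerate(series.action_ids):
        c = canonical[a]
        if c not in groups:
            groups[c] = []
            out_ids.append(c)
        groups[c].append(i)
    probs = np.column_stack(
        [series.probs[:, groups[c]].mean(axis=1) for c in out_ids]
    )
    return AnnotationSeries(probs, out_ids, series.tr_length_s)


def coordinate_time_series(
    series: AnnotationSeries, coords: ActionCoordinates
) -> DimensionTimeSeries:
    """Probability-weighted average of action coordinates per TR.

    Rows of the annotation matrix are renormalized to sum to one, so each
    TR's value is a convex combination of action coordinates.  A TR with
    zero total probability is an error.
    """
    missing = set(series.action_ids) - set(coords.action_ids)
    if missing:
        raise ValueError(
            f"annotation actions without coordinates: {sorted(missing)[:10]}"
        )
    totals = series.probs.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise ValueError(f"TRs with zero total annotation probability: {zero[:10]}")
    order = [coords.index_of(a) for a in series.action_ids]
    weights = series.probs / totals[:, None]
    values = weights @ coords.coords[order]
    return DimensionTimeSeries(values, series.tr_length_s)


def shift_for_hemodynamics(
    stimulus: np.ndarray, bold: np.ndarray, shift_trs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Align BOLD to stimulus for a fixed hemodynamic lag of ``shift_trs`` TRs.

    BOLD row ``t + shift_trs`` is paired with stimulus row ``t``; the
    overhanging rows (the last ``shift_trs`` of the stimulus, the first
    ``shift_trs`` of the BOLD) are dropped so both outputs have
    ``n_trs - shift_trs`` rows.
    """
    stimulus = np.asarray(stimulus)
    bold = np.asarray(bold)
    if stimulus.shape[0] != bold.shape[0]:
        raise ValueError("stimulus and BOLD must have the same TR count")
    n = stimulus.shape[0]
    if shift_trs < 0:
        raise ValueError("shift_trs must be nonnegative")
    if shift_trs >= n:
        raise ValueError(f"shift_trs={shift_trs} >= series length {n}")
    if shift_trs == 0:
        return stimulus.copy(), bold.copy()
    return stimulus[:-shift_trs].copy(), bold[shift_trs:].copy()


def segment_discrete_actions(series: AnnotationSeries) -> list[DiscreteAction]:
    """Split the series into maximal runs of the per-TR most-probable action.

    Argmax ties are broken toward the lowest action index (stable).  The
    returned runs tile [0, n_trs) with no gaps, and consecutive runs carry
    distinct action ids.
    """
    if series.n_trs == 0:
        raise ValueError("annotation series is empty")
    winners = np.argmax(series.probs, axis=1)
    boundaries = np.nonzero(np.diff(winners))[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [series.n_trs]))
    return [
        DiscreteAction(
            action_id=series.action_ids[winners[s]],
            start_tr=int(s),
            end_tr=int(e),
            tr_length_s=series.tr_length_s,
        )
        for s, e in zip(starts, ends)
    ]


def repeat_to_tr_resolution(
    series: AnnotationSeries, factor: int = 2
) -> AnnotationSeries:
    """Upsample annotation rows to TR resolution by repetition.

    Annotations produced on coarse (e.g. 3 s) video segments are expanded so
    that each segment row covers ``factor`` TRs (2 at a 1.5 s TR).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return AnnotationSeries(
        np.repeat(series.probs, factor, axis=0),
        list(series.action_ids),
        series.tr_length_s / factor if factor > 1 else series.tr_length_s,
    )
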