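"""End-to-end orchestration: config, input validation, the full run.

A ``PipelineConfig`` names the inputs (annotations, coordinates or raw
ratings, per-participant voxel matrices) and every tunable parameter, with
defaults matching the source study design: a 3-TR hemodynamic shift, five
contiguous video sections, top-5 scoring at lags 0-5.  ``run_full_pipeline``
executes aggregate -> shift -> bi-cross-validate -> report, writes all
outputs under ``out_dir`` and is byte-reproducible for a fixed config.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as afio
from .annotations import shift_for_hemodynamics
from .prediction import BiCVResult, bi_cross_validate
from .ratings import aggregate_ratings, exclude_raters
from .types import (
    DIMENSIONS,
    ActionCoordinates,
    AnnotationSeries,
    VoxelTimeSeries,
)

__version__ = "0.1.0"

logger = logging.getLogger("actfast")

__all__ = ["PipelineConfig", "Dataset", "load_inputs", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    """All paths, parameters and seeds of one reproducible run."""

    annotations: str = ""
    coordinates: str | None = None
    ratings: str | None = None
    voxels: list[str] = field(default_factory=list)
    mask: str | None = None
    out_dir: str = "actfast_out"

    tr_length_s: float = 1.5
    shift_trs: int = 3
    n_sections: int = 5
    k: int = 5
    max_lag: int = 5
    max_components: int = 20
    n_permutations: int = 1000
    dims: str = "all"  # "all" or one of the six dimension names
    alpha_items: str = "participants"
    procrustes_scaling: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dims != "all" and self.dims not in DIMENSIONS:
            raise ValueError(
                f"dims must be 'all' or one of {DIMENSIONS}, got {self.dims!r}"
            )
        if self.shift_trs < 0:
            raise ValueError("shift_trs must be nonnegative")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def dim_indices(self) -> list[int] | None:
        if self.dims == "all":
            return None
        return [DIMENSIONS.index(self.dims)]


@dataclass
class Dataset:
    annotations: AnnotationSeries
    coords: ActionCoordinates
    voxels: list[VoxelTimeSeries]


def load_inputs(config: PipelineConfig) -> Dataset:
    """Load and cross-validate all inputs named by the config.

    Enforces: annotation actions are a subset of coordinate actions; every
    participant matrix has the same TR count as the annotations; all
    participants share a voxel count; the hemodynamic shift leaves a
    non-empty series.
    """
    ann = afio.read_annotations(config.annotations)
    if config.coordinates:
        coords = afio.read_coordinates(config.coordinates)
    elif config.ratings:
        raw = afio.read_ratings(config.ratings)
        filtered, report = exclude_raters(raw)
        coords = aggregate_ratings(filtered, sorted(raw["action_id"].astype(str).unique()))
        logger.info("rating exclusion dropped %d raters", report.n_excluded)
    else:
        raise ValueError("config must name either coordinates or ratings")

    missing = set(ann.action_ids) - set(coords.action_ids)
    if missing:
        raise ValueError(
            f"annotations ({config.annotations}) contain actions absent from "
            f"coordinates: {sorted(missing)[:10]}"
        )
    if not config.voxels:
        raise ValueError("config names no voxel files")
    voxels = [afio.read_voxels(p, mask_path=config.mask) for p in config.voxels]
    n_vox = {v.n_voxels for v in voxels}
    if len(n_vox) > 1:
        raise ValueError(f"participants disagree on voxel count: {sorted(n_vox)}")
    for v, p in zip(voxels, config.voxels):
        if v.n_trs != ann.n_trs:
            raise ValueError(
                f"TR mismatch: {p} has {v.n_trs} TRs but {config.annotations} "
                f"has {ann.n_trs}"
            )
    if config.shift_trs >= ann.n_trs:
        raise ValueError("hemodynamic shift consumes the whole series")
    return Dataset(annotations=ann, coords=coords, voxels=voxels)


def _apply_shift(ds: Dataset, shift_trs: int) -> Dataset:
    if shift_trs == 0:
        return ds
    probs, _ = shift_for_hemodynamics(
        ds.annotations.probs, ds.annotations.probs, shift_trs
    )
    ann = AnnotationSeries(probs, list(ds.annotations.action_ids), ds.annotations.tr_length_s)
    voxels = []
    for v in ds.voxels:
        _, bold = shift_for_hemodynamics(ds.annotations.probs, v.data, shift_trs)
        voxels.append(VoxelTimeSeries(v.participant_id, bold, v.tr_length_s))
    return Dataset(annotations=ann, coords=ds.coords, voxels=voxels)


def _results_tables(result: BiCVResult, out_dir: Path, config: PipelineConfig) -> dict:
    lags = list(range(config.max_lag + 1))
    rows = []
    for f in result.folds:
        for L in lags:
            rows.append(
                {
                    "section": f.test_section,
                    "participant": f.test_participant,
                    "lag": L,
                    "k": config.k,
                    "accuracy": f.observed[L],
                    "n_instances": int(f.counts[L]),
                    "p_value": f.p_values[L],
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "results_long.tsv", sep="\t", index=False)

    summary = {
        "k": config.k,
        "lags": lags,
        "observed_accuracy": result.pooled.observed_accuracy.tolist(),
        "null_mean": result.pooled.null_distribution.mean(axis=0).tolist(),
        "null_p975": np.percentile(
            result.pooled.null_distribution, 97.5, axis=0
        ).tolist(),
        "group_p_values": result.pooled.p_values.tolist(),
        "participant_p_values": {
            p: v.tolist() for p, v in result.participant_p.items()
        },
        "fraction_participants_significant": (
            result.fraction_participants_significant.tolist()
        ),
        "n_instances": result.pooled.n_instances.tolist(),
        "n_candidates": result.n_candidates,
        "config": result.config,
        "model_hashes": {
            f"s{f.test_section}_{f.test_participant}": f.model_hash
            for f in result.folds
        },
    }
    afio.write_json(out_dir / "results.json", summary)
    return summary


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole analysis and write results under ``config.out_dir``.

    Returns the summary dict that was written to ``results.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "load_inputs"
    try:
        ds = load_inputs(config)
        logger.info(
            "loaded %d TRs x %d actions, %d participants",
            ds.annotations.n_trs,
            ds.annotations.n_actions,
            len(ds.voxels),
        )
        stage = "hemodynamic_shift"
        ds = _apply_shift(ds, config.shift_trs)
        stage = "bi_cross_validate"
        result = bi_cross_validate(
            ds.annotations,
            ds.coords,
            ds.voxels,
            n_sections=config.n_sections,
            k=config.k,
            max_lag=config.max_lag,
            max_components=config.max_components,
            n_permutations=config.n_permutations,
            dims=config.dim_indices(),
            alpha_items=config.alpha_items,
            procrustes_scaling=config.procrustes_scaling,
            seed=config.seed,
        )
        stage = "report"
        summary = _results_tables(result, out_dir, config)
        afio.write_json(
            out_dir / "provenance.json",
            {
                "config": config.to_dict(),
                "config_hash": config.content_hash(),
                "seed": config.seed,
                "version": __version__,
                "elapsed_s": round(time.time() - t0, 3),
            },
        )
        config.to_yaml(out_dir / "config.yaml")
        return summary
    except Exception:
        logger.exception("pipeline failed in stage %s", stage)
        raise
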