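"""Write/read a complete synthetic study bundle to disk.

The bundle is what the ``simulate`` CLI subcommand produces and what
``PipelineConfig`` consumes: annotations, planted coordinates, a raw
ratings table, per-participant voxel matrices and a ground-truth JSON
(sequence, reliable-voxel mask, seeds) for later verification.
"""
from __future__ import annotations

from pathlib import Path

from . import io as afio
from .pipeline import PipelineConfig
from .synthetic import build_world, generate_ratings

__all__ = ["simulate_bundle"]


def simulate_bundle(
    out_dir: str | Path,
    fmt: str = "tsv",
    n_actions: int = 332,
    n_trs: int = 2000,
    n_participants: int = 4,
    n_voxels: int = 200,
    n_reliable: int = 100,
    temperature: float = 0.3,
    concentration: float = 0.6,
    noise_sd: float = 0.3,
    n_raters_per_dim: int = 20,
    rater_noise_sd: float = 1.0,
    n_degenerate: int = 3,
    tr_length_s: float = 1.5,
    seed: int = 0,
) -> PipelineConfig:
    """Generate a synthetic world and write it as a loadable input bundle.

    Returns a ready-to-run ``PipelineConfig`` pointing at the written
    files (with ``shift_trs=0`` — the simulator builds no hemodynamic lag
    into the data).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world, annotations, voxels = build_world(
        n_actions=n_actions,
        n_trs=n_trs,
        n_participants=n_participants,
        n_voxels=n_voxels,
        n_reliable=n_reliable,
        temperature=temperature,
        concentration=concentration,
        noise_sd=noise_sd,
        tr_length_s=tr_length_s,
        seed=seed,
    )
    afio.write_annotations(out / "annotations.tsv", annotations)
    afio.write_coordinates(out / "coordinates.tsv", world.coordinates())
    ratings = generate_ratings(
        world.coordinates(),
        n_raters_per_dim=n_raters_per_dim,
        rater_noise_sd=rater_noise_sd,
        n_degenerate=n_degenerate,
        seed=seed,
    )
    afio.write_ratings(out / "ratings.csv", ratings)

    suffix = {"tsv": ".tsv", "npz": ".npz", "nifti": ".nii.gz"}[fmt]
    voxel_paths: list[str] = []
    for v in voxels:
        p = out / f"{v.participant_id}{suffix}"
        afio.write_voxels(p, v, fmt=fmt)
        voxel_paths.append(str(p))

    afio.write_json(
        out / "ground_truth.json",
        {
            "seed": seed,
            "n_actions": n_actions,
            "sequence": [[a, int(d)] for a, d in world.sequence],
            "reliable_voxel_mask": world.reliable_voxel_mask.astype(int).tolist(),
            "parameters": {
                "temperature": temperature,
                "concentration": concentration,
                "noise_sd": noise_sd,
                "n_voxels": n_voxels,
                "n_reliable": n_reliable,
                "tr_length_s": tr_length_s,
            },
        },
    )
    return PipelineConfig(
        annotations=str(out / "annotations.tsv"),
        coordinates=str(out / "coordinates.tsv"),
        voxels=voxel_paths,
        out_dir=str(out / "results"),
        tr_length_s=tr_length_s,
        shift_trs=0,
        seed=seed,
    )
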