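"""Readers and writers for the pipeline's file dialects.

Text-first: annotations and coordinates are TSV, ratings CSV, reports
JSON.  Large voxel matrices may alternatively travel as compressed ``.npz``
arrays or as 4-D NIfTI volumes with a binary mask; all three dialects load
to the same in-memory ``VoxelTimeSeries`` (voxels in C-order within the
mask), so downstream results are dialect-independent.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ActionCoordinates, AnnotationSeries, DiscreteAction, VoxelTimeSeries

__all__ = [
    "write_annotations",
    "read_annotations",
    "write_coordinates",
    "read_coordinates",
    "write_ratings",
    "read_ratings",
    "write_voxels",
    "read_voxels",
    "write_discrete_actions",
    "write_json",
    "read_json",
]


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_annotations(path: str | Path, series: AnnotationSeries) -> None:
    path = Path(path)
    header = "\t".join(series.action_ids)
    with open(path, "w") as fh:
        fh.write(f"# tr_length_s={series.tr_length_s}\n")
        fh.write(header + "\n")
        np.savetxt(fh, series.probs, fmt="%.10g", delimiter="\t")


def read_annotations(path: str | Path) -> AnnotationSeries:
    path = Path(path)
    tr_length = 1.5
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "tr_length_s=" in first:
                tr_length = float(first.split("tr_length_s=")[1])
            header = fh.readline()
        else:
            header = first
        ids = header.rstrip("\n").split("\t")
        try:
            probs = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as e:
            raise ValueError(f"{path}: cannot parse annotation matrix: {e}") from e
    if probs.shape[1] != len(ids):
        raise ValueError(
            f"{path}: {len(ids)} header columns but {probs.shape[1]} data columns"
        )
    return AnnotationSeries(probs, ids, tr_length_s=tr_length)


def write_coordinates(path: str | Path, coords: ActionCoordinates) -> None:
    df = pd.DataFrame(coords.coords, columns=list(coords.dimensions))
    df.insert(0, "action_id", coords.action_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_coordinates(path: str | Path, provenance: str = "rated") -> ActionCoordinates:
    df = pd.read_csv(path, sep="\t")
    if "action_id" not in df.columns:
        raise ValueError(f"{path}: missing 'action_id' column")
    dims = [c for c in df.columns if c != "action_id"]
    return ActionCoordinates(
        df["action_id"].astype(str).tolist(),
        df[dims].to_numpy(float),
        provenance=provenance,
        dimensions=tuple(dims),
    )


def write_ratings(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_ratings(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"rater_id", "action_id", "dimension", "rating"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: ratings file missing columns {sorted(missing)}")
    return table


# ---------------------------------------------------------------------------
# voxel dialects


def _nifti_grid(n_voxels: int) -> tuple[int, int, int]:
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    return side, side, max(1, int(np.ceil(n_voxels / side**2)))


def write_voxels(
    path: str | Path,
    series: VoxelTimeSeries,
    fmt: str = "tsv",
    mask_path: str | Path | None = None,
) -> None:
    """Write one participant's matrix as ``tsv``, ``npz`` or ``nifti``.

    The NIfTI dialect packs voxels into a synthetic cuboid grid (this is
    simulated data with no anatomy); ``mask_path`` names the companion
    binary mask volume and defaults to ``<path>_mask.nii.gz``.
    """
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# participant={series.participant_id} tr_length_s={series.tr_length_s}\n")
            np.savetxt(fh, series.data, fmt="%.10g", delimiter="\t")
    elif fmt == "npz":
        np.savez_compressed(
            path,
            data=series.data,
            participant_id=series.participant_id,
            tr_length_s=series.tr_length_s,
        )
    elif fmt == "nifti":
        import nibabel as nib

        n_trs, n_vox = series.data.shape
        nx, ny, nz = _nifti_grid(n_vox)
        mask = np.zeros(nx * ny * nz, dtype=np.uint8)
        mask[:n_vox] = 1
        vol = np.zeros((nx * ny * nz, n_trs), dtype=np.float64)
        vol[:n_vox] = series.data.T
        img = nib.Nifti1Image(vol.reshape(nx, ny, nz, n_trs), affine=np.eye(4))
        img.header["pixdim"][4] = series.tr_length_s
        nib.save(img, str(path))
        mask_img = nib.Nifti1Image(mask.reshape(nx, ny, nz), affine=np.eye(4))
        nib.save(mask_img, str(mask_path or _default_mask_path(path)))
    else:
        raise ValueError(f"unknown voxel format {fmt!r}")


def _default_mask_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + "_mask" + suffix)
    return path.with_name(name + "_mask.nii.gz")


def read_voxels(
    path: str | Path,
    fmt: str | None = None,
    mask_path: str | Path | None = None,
    participant_id: str | None = None,
) -> VoxelTimeSeries:
    """Load a voxel matrix; the dialect is inferred from the suffix when
    ``fmt`` is not given."""
    path = Path(path)
    if fmt is None:
        name = path.name
        if name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif name.endswith(".npz"):
            fmt = "npz"
        else:
            fmt = "tsv"
    if fmt == "tsv":
        tr_length = 1.5
        pid = participant_id or path.stem
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                if "tr_length_s=" in first:
                    tr_length = float(first.split("tr_length_s=")[1].split()[0])
                if "participant=" in first and participant_id is None:
                    pid = first.split("participant=")[1].split()[0]
            else:
                fh.seek(0)
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        return VoxelTimeSeries(pid, data, tr_length_s=tr_length)
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as z:
            return VoxelTimeSeries(
                participant_id or str(z["participant_id"]),
                z["data"],
                tr_length_s=float(z["tr_length_s"]),
            )
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        mask_img = nib.load(str(mask_path or _default_mask_path(path)))
        mask = np.asarray(mask_img.dataobj).astype(bool)
        data4d = np.asarray(img.dataobj)
        if data4d.ndim != 4:
            raise ValueError(f"{path}: expected 4-D NIfTI, got {data4d.ndim}-D")
        data = data4d[mask].T  # (n_trs, n_voxels), C-order within the mask
        tr = float(img.header["pixdim"][4]) or 1.5
        return VoxelTimeSeries(participant_id or path.name.split(".")[0], data, tr_length_s=tr)
    raise ValueError(f"unknown voxel format {fmt!r}")


def write_discrete_actions(path: str | Path, runs: list[DiscreteAction]) -> None:
    with open(path, "w") as fh:
        fh.write("action_id\tstart_tr\tend_tr\tduration_s\n")
        for r in runs:
            fh.write(f"{r.action_id}\t{r.start_tr}\t{r.end_tr}\t{r.duration_s:.6g}\n")
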