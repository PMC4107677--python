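"""On-disk formats: NIfTI-1 volumes, motion tables, phenotype and cluster TSVs.

Volumes go through nibabel. The time axis is the fourth NIfTI dimension on
disk and the first axis in memory (time-major). All tables are TSV with '.'
decimal separator, independent of locale.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import TYPE_CHECKING

import nibabel as nib
import numpy as np
import pandas as pd

from .core import LabelVolume, Bold4D, VolumeGrid

if TYPE_CHECKING:  # pragma: no cover
    from .report import ClusterReport

__all__ = [
    "read_bold",
    "write_bold",
    "read_label_volume",
    "write_label_volume",
    "read_motion",
    "write_motion",
    "read_phenotypes",
    "write_phenotypes",
    "write_cluster_table",
    "read_cluster_table",
    "CLUSTER_TABLE_COLUMNS",
]

PHENOTYPE_COLUMNS = ["subject_id", "age_years", "sex", "site", "bold_path", "motion_path"]

CLUSTER_TABLE_COLUMNS = [
    "cluster_id", "contrast", "n_voxels",
    "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_t", "p_fwe",
    "mean_r_young", "mean_r_old", "t_delta_r", "spearman_age",
]


def _grid_from_header(img: nib.Nifti1Image, path: os.PathLike) -> VolumeGrid:
    zooms = img.header.get_zooms()
    if len(zooms) < 4 or zooms[3] <= 0:
        raise ValueError(f"{path}: header field tr_seconds (pixdim[4]) must be positive, got {zooms[3:4]}")
    return VolumeGrid(
        shape=img.shape[:3],
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        affine=img.affine,
        tr_seconds=float(zooms[3]),
    )


def read_bold(path: str | os.PathLike) -> Bold4D:
    """Read a 4-D NIfTI-1 BOLD series into time-major memory order.

    Raises a descriptive error for a missing file, wrong dimensionality
    or a non-positive TR in the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"BOLD file not found: {path}")
    img = nib.load(path)
    if img.ndim != 4:
        raise ValueError(f"{path}: expected 4 dimensions (x,y,z,time), got {img.ndim}")
    grid = _grid_from_header(img, path)
    data = np.asarray(img.dataobj, dtype=np.float64).transpose(3, 0, 1, 2)
    return Bold4D(grid=grid, data=data, subject_id=path.name.split("_")[0])


def write_bold(bold: Bold4D, path: str | os.PathLike) -> None:
    data = np.asarray(bold.data, dtype=np.float64).transpose(1, 2, 3, 0)
    img = nib.Nifti1Image(data, affine=bold.grid.affine)
    img.header.set_zooms((*bold.grid.voxel_size_mm, bold.grid.tr_seconds))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def write_zmap(grid: VolumeGrid, values: np.ndarray, path: str | os.PathLike) -> None:
    """Write a 3-D statistical/connectivity volume."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine=grid.affine)
    img.header.set_zooms(grid.voxel_size_mm)
    nib.save(img, str(path))


def read_zmap(path: str | os.PathLike, tr_seconds: float = 1.0) -> tuple[VolumeGrid, np.ndarray]:
    """Read a 3-D volume back as ``(grid, values)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(path)
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {img.ndim} dims")
    grid = VolumeGrid(
        shape=img.shape,
        voxel_size_mm=tuple(float(z) for z in img.header.get_zooms()[:3]),
        affine=img.affine,
        tr_seconds=tr_seconds,
    )
    return grid, np.asarray(img.dataobj, dtype=np.float64)


def _legend_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            name = name[: -len(suf)]
            break
    return path.with_name(name + ".labels.tsv")


def write_label_volume(atlas: LabelVolume, path: str | os.PathLike) -> None:
    """Write labels as int16 NIfTI plus a ``<stem>.labels.tsv`` legend sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), affine=atlas.grid.affine)
    img.header.set_zooms((*atlas.grid.voxel_size_mm, 0.0)[:3])
    nib.save(img, str(path))
    legend = pd.DataFrame(
        sorted(atlas.legend.items()), columns=["label", "role"]
    )
    legend.to_csv(_legend_path(path), sep="\t", index=False)


def read_label_volume(path: str | os.PathLike, tr_seconds: float = 1.0) -> LabelVolume:
    """Read a label volume and its legend sidecar.

    ``tr_seconds`` is a placeholder for the (purely spatial) atlas grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label volume not found: {path}")
    img = nib.load(path)
    if img.ndim != 3:
        raise ValueError(f"{path}: label volume must be 3-D, got {img.ndim} dims")
    legend_path = _legend_path(path)
    if not legend_path.exists():
        raise FileNotFoundError(f"legend sidecar not found: {legend_path}")
    legend_df = pd.read_csv(legend_path, sep="\t")
    legend = {int(r.label): str(r.role) for r in legend_df.itertuples()}
    grid = VolumeGrid(
        shape=img.shape,
        voxel_size_mm=tuple(float(z) for z in img.header.get_zooms()[:3]),
        affine=img.affine,
        tr_seconds=tr_seconds,
    )
    return LabelVolume(grid=grid, labels=np.asarray(img.dataobj).astype(np.int64), legend=legend)


def read_motion(path: str | os.PathLike) -> np.ndarray:
    """Read a whitespace-delimited T x 6 realignment-parameter file.

    Columns are 3 translations (mm) then 3 rotations (radians).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"motion file not found: {path}")
    table = np.loadtxt(path, ndmin=2)
    if table.shape[1] != 6:
        raise ValueError(f"{path}: motion table must have 6 columns, got {table.shape[1]}")
    return table


def write_motion(motion: np.ndarray, path: str | os.PathLike) -> None:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion table must be T x 6, got {motion.shape}")
    np.savetxt(path, motion, fmt="%.8e")


def _validate_phenotypes(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{origin}: missing required column(s) {missing}")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{origin}: duplicated subject_id {sorted(set(dup))}")
    try:
        df["age_years"] = df["age_years"].astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{origin}: column age_years not parseable as numbers ({err})") from None
    if (df["age_years"] <= 0).any():
        bad = df.loc[df["age_years"] <= 0, "subject_id"].tolist()
        raise ValueError(f"{origin}: non-positive age for subject(s) {bad}")
    if df["age_years"].nunique() < 2:
        raise ValueError(f"{origin}: need at least 2 distinct ages")
    df["sex"] = pd.Categorical(df["sex"].astype(str))
    if len(df["sex"].cat.categories) > 2:
        raise ValueError(f"{origin}: sex must be binary, got {list(df['sex'].cat.categories)}")
    df["site"] = pd.Categorical(df["site"].astype(str))
    counts = df["site"].value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"{origin}: every site needs >=2 subjects, too few in {small}")
    return df


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate the cohort phenotype TSV, preserving row order.

    Columns: subject_id, age_years, sex, site, bold_path, motion_path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"phenotype table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    return _validate_phenotypes(df, str(path))


def write_phenotypes(df: pd.DataFrame, path: str | os.PathLike) -> None:
    _validate_phenotypes(df, "phenotypes").to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def write_cluster_table(report: "ClusterReport", path: str | os.PathLike) -> None:
    """Write a per-cluster statistics table (one row per finalized cluster).

    Peak coordinates are world mm obtained via the grid affine. Raises if
    any cluster lacks its statistics (i.e. the report is not finalized).
    """
    rows = report.to_rows()
    df = pd.DataFrame(rows, columns=CLUSTER_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_cluster_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
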