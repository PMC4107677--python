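"""Seed time series extraction and per-subject Fisher-Z connectivity maps.

The representative time series of a region is its first eigenvariate: the
first left singular vector of the time x voxel matrix of mean-centered
voxel series, rescaled to unit variance and sign-aligned with the region's
spatial-mean series. For the main analysis both hemispheric seed ROIs are
collapsed into one seed by computing the eigenvariate over the union of
their voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ROLE_SEED_LEFT, ROLE_SEED_RIGHT, Bold4D, LabelVolume, VolumeGrid

__all__ = [
    "SeedSeries",
    "FCMap",
    "R_CLIP",
    "extract_eigenvariate",
    "collapse_bilateral_seed",
    "fc_zmap",
]

# |r| is clipped here before atanh so Fisher-Z maps stay finite.
R_CLIP = 1.0 - 1e-7


@dataclass
class SeedSeries:
    """Unit-variance representative series of a seed region."""

    values: np.ndarray
    source: str  # bilateral | left | right
    n_voxels_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("seed series must be 1-D")
        if abs(self.values.std(ddof=0) - 1.0) > 1e-8:
            raise ValueError("seed series must have unit variance")


@dataclass
class FCMap:
    """Voxel-wise Fisher-Z seed connectivity map for one subject.

    ``z_values`` is 0 exactly outside ``mask``.
    """

    grid: VolumeGrid
    z_values: np.ndarray
    mask: np.ndarray
    subject_id: str
    seed_source: str

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.z_values.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise ValueError("z_values/mask shape must match grid")
        if not np.all(np.isfinite(self.z_values[self.mask])):
            raise ValueError("non-finite z inside mask")
        if np.any(self.z_values[~self.mask] != 0):
            raise ValueError("z must be exactly 0 outside mask")


def extract_eigenvariate(bold: Bold4D, seed_mask: np.ndarray, source: str = "bilateral") -> SeedSeries:
    """First eigenvariate of the seed voxels' time series.

    Computed as the first left singular vector of the T x V matrix of
    mean-centered voxel series, rescaled to unit (population) variance.
    Sign convention: positive correlation with the spatial-mean series;
    if that correlation is exactly 0, the first nonzero element is made
    positive (deterministic tie-break).
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != bold.grid.shape:
        raise ValueError("seed mask shape must match grid")
    M = bold.data.reshape(bold.n_volumes, -1)[:, seed_mask.ravel()]
    if M.shape[1] == 0:
        raise ValueError("seed mask is empty")
    M = M - M.mean(axis=0)
    if not np.any(M.std(axis=0) > 0):
        raise ValueError("all seed voxels are constant; no eigenvariate exists")
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    u1 = U[:, 0]
    spatial_mean = M.mean(axis=1)
    align = float(u1 @ spatial_mean)
    if align < 0:
        u1 = -u1
    elif align == 0:
        nz = np.flatnonzero(u1)
        if nz.size and u1[nz[0]] < 0:
            u1 = -u1
    values = u1 / u1.std(ddof=0)
    return SeedSeries(values=values, source=source, n_voxels_used=M.shape[1])


def collapse_bilateral_seed(bold: Bold4D, atlas: LabelVolume) -> SeedSeries:
    """Common bilateral seed: eigenvariate over the union of left+right voxels."""
    left = atlas.mask(ROLE_SEED_LEFT)
    right = atlas.mask(ROLE_SEED_RIGHT)
    if not left.any() or not right.any():
        raise ValueError("both seed ROIs must be non-empty to collapse them")
    return extract_eigenvariate(bold, left | right, source="bilateral")


def seed_series(bold: Bold4D, atlas: LabelVolume, source: str) -> SeedSeries:
    """Seed series for a named source.

    ``bilateral`` is the eigenvariate of the union of both ROIs (the
    default); ``bilateral_mean`` averages the two per-hemisphere
    eigenvariates instead (a sensitivity-check alternative); ``left`` /
    ``right`` use a single ROI.
    """
    if source == "bilateral":
        return collapse_bilateral_seed(bold, atlas)
    if source == "bilateral_mean":
        left = extract_eigenvariate(bold, atlas.mask(ROLE_SEED_LEFT), source="left")
        right = extract_eigenvariate(bold, atlas.mask(ROLE_SEED_RIGHT), source="right")
        mean = (left.values + right.values) / 2.0
        sd = mean.std(ddof=0)
        if sd == 0:
            raise ValueError("left and right eigenvariates cancel exactly")
        return SeedSeries(values=mean / sd, source="bilateral_mean",
                          n_voxels_used=left.n_voxels_used + right.n_voxels_used)
    if source == "left":
        return extract_eigenvariate(bold, atlas.mask(ROLE_SEED_LEFT), source="left")
    if source == "right":
        return extract_eigenvariate(bold, atlas.mask(ROLE_SEED_RIGHT), source="right")
    raise ValueError(f"unknown seed source {source!r}")


def fc_zmap(bold: Bold4D, seed: SeedSeries, gm_mask: np.ndarray) -> FCMap:
    """Pearson-correlate the seed with every in-mask voxel; Fisher-transform.

    r is clipped to |r| <= 1 - 1e-7 before atanh. Zero-variance voxels get
    z = 0 and are removed from the map's mask.
    """
    gm_mask = np.asarray(gm_mask, dtype=bool)
    if seed.values.shape[0] != bold.n_volumes:
        raise ValueError(
            f"seed length {seed.values.shape[0]} does not match series length {bold.n_volumes}"
        )
    if not gm_mask.any():
        raise ValueError("analysis mask is empty")
    T = bold.n_volumes
    Y = bold.data.reshape(T, -1)[:, gm_mask.ravel()]
    Yc = Y - Y.mean(axis=0)
    sd = Yc.std(axis=0)
    sc = seed.values - seed.values.mean()
    s_sd = sc.std()
    ok = sd > 0
    r = np.zeros(Y.shape[1])
    r[ok] = (sc @ Yc[:, ok]) / (T * s_sd * sd[ok])
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    z[~ok] = 0.0

    z_vol = np.zeros(bold.grid.shape)
    z_vol[gm_mask] = z
    out_mask = gm_mask.copy()
    out_mask[gm_mask] = ok
    z_vol[~out_mask] = 0.0
    return FCMap(
        grid=bold.grid, z_values=z_vol, mask=out_mask,
        subject_id=bold.subject_id, seed_source=seed.source,
    )
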