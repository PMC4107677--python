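"""Core in-memory containers shared by every pipeline stage.

All volumes live on a :class:`VolumeGrid` (shape, voxel size, affine, TR).
Voxel indices are 0-based everywhere; world coordinates (mm) are obtained
only by applying the grid affine, so no 1-based convention ever reaches
output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeGrid",
    "Bold4D",
    "LabelVolume",
    "ROLE_SEED_LEFT",
    "ROLE_SEED_RIGHT",
    "ROLE_GM",
    "ROLE_WM",
    "ROLE_CSF",
]

ROLE_SEED_LEFT = "seed_left"
ROLE_SEED_RIGHT = "seed_right"
ROLE_GM = "gm"
ROLE_WM = "wm"
ROLE_CSF = "csf"

_TISSUE_ROLES = (ROLE_GM, ROLE_WM, ROLE_CSF)


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3-D sampling grid plus the temporal sampling interval.

    Parameters
    ----------
    shape
        Number of voxels along x, y, z.
    voxel_size_mm
        Voxel edge lengths in mm; must equal the column norms of the
        affine's 3x3 block.
    affine
        4x4 matrix mapping 0-based voxel indices to world mm.
    tr_seconds
        Repetition time (sampling interval of the time axis), seconds.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vox = tuple(float(v) for v in self.voxel_size_mm)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size_mm", vox)
        aff = np.asarray(self.affine, dtype=float)
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "tr_seconds", float(self.tr_seconds))
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        if any(v <= 0 for v in vox):
            raise ValueError(f"voxel_size_mm must be positive, got {vox}")
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine is singular")
        col_norms = np.linalg.norm(aff[:3, :3], axis=0)
        if not np.allclose(col_norms, vox, atol=1e-6):
            raise ValueError(
                f"voxel_size_mm {vox} does not match affine column norms {col_norms}"
            )
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")

    @classmethod
    def isotropic(
        cls, shape: tuple[int, int, int], voxel_mm: float, tr_seconds: float
    ) -> "VolumeGrid":
        """Axis-aligned grid with equal voxel size on every axis."""
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(shape=tuple(shape), voxel_size_mm=(voxel_mm,) * 3,
                   affine=aff, tr_seconds=tr_seconds)

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (..., 3) to world mm via the affine."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        hom = np.c_[idx, np.ones(len(idx))]
        out = (self.affine @ hom.T).T[:, :3]
        return out[0] if np.asarray(index).ndim == 1 else out

    def same_space(self, other: "VolumeGrid", *, atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class Bold4D:
    """A subject's 4-D BOLD series, stored time-major as (T, X, Y, Z)."""

    grid: VolumeGrid
    data: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-D (T,X,Y,Z), got ndim={self.data.ndim}")
        if self.data.shape[0] < 2:
            raise ValueError(f"need T >= 2 volumes, got T={self.data.shape[0]}")
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError(
                f"spatial shape {self.data.shape[1:]} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    def with_data(self, data: np.ndarray) -> "Bold4D":
        return Bold4D(grid=self.grid, data=data, subject_id=self.subject_id)


@dataclass
class LabelVolume:
    """Integer-coded atlas marking seed ROIs, tissue classes and effect regions.

    ``legend`` maps each nonzero label to a role string: ``seed_left``,
    ``seed_right``, ``gm``, ``wm``, ``csf`` or any other name (used for the
    synthetic effect regions, which are treated as gray matter by analysis
    masks).
    """

    grid: VolumeGrid
    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError(
                f"labels shape {self.labels.shape} does not match grid {self.grid.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from legend")
        for role in (ROLE_SEED_LEFT, ROLE_SEED_RIGHT):
            if not self.mask(role).any():
                raise ValueError(f"required ROI '{role}' is empty")

    def labels_for(self, role: str) -> list[int]:
        return [lab for lab, r in self.legend.items() if r == role]

    def mask(self, role: str) -> np.ndarray:
        """Boolean mask of all voxels whose label maps to ``role``."""
        labs = self.labels_for(role)
        if not labs:
            return np.zeros(self.grid.shape, dtype=bool)
        return np.isin(self.labels, labs)

    def effect_roles(self) -> list[str]:
        known = {ROLE_SEED_LEFT, ROLE_SEED_RIGHT, *_TISSUE_ROLES}
        return sorted(set(self.legend.values()) - known)

    def gm_analysis_mask(self) -> np.ndarray:
        """Analysis mask: GM background plus effect regions plus both seeds.

        Seed voxels are retained (they trivially show high connectivity);
        WM/CSF compartments are excluded.
        """
        m = self.mask(ROLE_GM) | self.mask(ROLE_SEED_LEFT) | self.mask(ROLE_SEED_RIGHT)
        for role in self.effect_roles():
            m |= self.mask(role)
        return m
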