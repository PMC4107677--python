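"""Per-subject signal conditioning.

Fixed stage order: discard initial volumes -> spatial smoothing -> nuisance
regression -> band-pass. The nuisance model has 16 nominal columns
(intercept, 6 motion parameters, their 6 backward-difference derivatives,
and 3 tissue-mean series); constant columns are dropped with a warning.

The band-pass is an ideal discrete-Fourier mask: every DFT coefficient
whose frequency lies in [low, high] is kept at unit gain, all others
(including DC) are zeroed. This realization is zero-phase, idempotent
(it is an orthogonal projection) and has an exactly flat passband.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ROLE_CSF, ROLE_GM, ROLE_SEED_LEFT, ROLE_SEED_RIGHT, ROLE_WM, Bold4D, LabelVolume

__all__ = [
    "PreprocConfig",
    "NuisanceDesign",
    "discard_initial_volumes",
    "smooth_fwhm",
    "build_nuisance_design",
    "residualize",
    "bandpass",
    "preprocess_subject",
]

FWHM_TO_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))  # ~2.3548


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing knobs.

    n_discard
        Initial volumes dropped for T1 saturation (default 4).
    fwhm_mm
        Gaussian spatial smoothing kernel FWHM in mm (default 5; 0 = off).
    band_hz
        Band-pass passband in Hz (default 0.01-0.08); must lie strictly
        inside (0, Nyquist) for the series TR.
    """

    n_discard: int = 4
    fwhm_mm: float = 5.0
    band_hz: tuple[float, float] = (0.01, 0.08)

    def __post_init__(self) -> None:
        low, high = self.band_hz
        if self.n_discard < 0:
            raise ValueError("n_discard must be non-negative")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be non-negative")
        if not 0 < low < high:
            raise ValueError(f"band must satisfy 0 < low < high, got {self.band_hz}")


@dataclass
class NuisanceDesign:
    """T x K nuisance regressor matrix with column bookkeeping.

    Non-intercept columns are mean-centered. ``dropped_columns`` lists
    nominal columns removed because they were constant over the series.
    """

    matrix: np.ndarray
    column_names: list[str]
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def discard_initial_volumes(
    bold: Bold4D, n_discard: int, motion: np.ndarray | None = None
) -> Bold4D | tuple[Bold4D, np.ndarray]:
    """Drop the first ``n_discard`` volumes (saturation window).

    If a motion table is given its leading rows are dropped identically
    and the pair is returned.
    """
    if bold.n_volumes <= n_discard:
        raise ValueError(
            f"cannot discard {n_discard} volumes from a series of length {bold.n_volumes}"
        )
    out = bold.with_data(bold.data[n_discard:])
    if motion is None:
        return out
    if motion.shape[0] != bold.n_volumes:
        raise ValueError(
            f"motion rows ({motion.shape[0]}) must match series length before discard ({bold.n_volumes})"
        )
    return out, motion[n_discard:]


def smooth_fwhm(bold: Bold4D, fwhm_mm: float) -> Bold4D:
    """Volume-wise separable Gaussian smoothing with reflect boundary.

    Per-axis sigma in voxels is fwhm_mm / (sqrt(8 ln 2) * voxel_size_mm).
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return bold
    sigma_vox = [fwhm_mm / (FWHM_TO_SIGMA * v) for v in bold.grid.voxel_size_mm]
    out = ndimage.gaussian_filter(
        bold.data, sigma=[0.0, *sigma_vox], mode="reflect"
    )
    return bold.with_data(out)


def _tissue_class_mask(atlas: LabelVolume, role: str) -> np.ndarray:
    # GM class includes seeds and synthetic effect regions: they are
    # gray-matter voxels for the purpose of the tissue-mean regressor.
    if role == ROLE_GM:
        return atlas.gm_analysis_mask()
    return atlas.mask(role)


def build_nuisance_design(
    motion: np.ndarray, bold: Bold4D, tissues: LabelVolume
) -> NuisanceDesign:
    """Assemble the 16-column nuisance model for one subject.

    Columns: intercept; the 6 realignment parameters; their backward
    differences (first element 0); the GM/WM/CSF mean series, obtained by
    averaging at each time point over all voxels of the tissue class.
    Motion rows must already be truncated to the (post-discard) series
    length. Constant columns are dropped with a warning.
    """
    T = bold.n_volumes
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (T, 6):
        raise ValueError(f"motion must be {T} x 6 (post-discard), got {motion.shape}")
    cols: list[np.ndarray] = [np.ones(T)]
    names = ["intercept"]
    for j in range(6):
        cols.append(motion[:, j])
        names.append(f"motion_{j + 1}")
    deriv = np.diff(motion, axis=0, prepend=motion[:1])
    for j in range(6):
        cols.append(deriv[:, j])
        names.append(f"motion_deriv_{j + 1}")
    flat = bold.data.reshape(T, -1)
    for role in (ROLE_GM, ROLE_WM, ROLE_CSF):
        mask = _tissue_class_mask(tissues, role).ravel()
        if not mask.any():
            raise ValueError(f"tissue class '{role}' has no voxels in the atlas")
        cols.append(flat[:, mask].mean(axis=1))
        names.append(f"{role}_mean")

    matrix = np.column_stack(cols)
    matrix[:, 1:] -= matrix[:, 1:].mean(axis=0)

    keep = [0] + [j for j in range(1, matrix.shape[1])
                  if np.ptp(matrix[:, j]) > 0]
    dropped = [names[j] for j in range(matrix.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(
            f"dropping constant nuisance column(s): {dropped}", stacklevel=2
        )
    return NuisanceDesign(
        matrix=matrix[:, keep],
        column_names=[names[j] for j in keep],
        dropped_columns=dropped,
    )


def residualize(bold: Bold4D, design: NuisanceDesign) -> Bold4D:
    """Replace every voxel series with its least-squares residual.

    The intercept stays in the design, so residuals are mean-zero and
    orthogonal to every retained column.
    """
    X = design.matrix
    T = bold.n_volumes
    if X.shape[0] != T:
        raise ValueError(f"design has {X.shape[0]} rows, series has {T} volumes")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "nuisance design is rank-deficient after dropping constant columns; "
            f"columns: {design.column_names}"
        )
    Q, _ = np.linalg.qr(X)
    flat = bold.data.reshape(T, -1)
    resid = flat - Q @ (Q.T @ flat)
    return bold.with_data(resid.reshape(bold.data.shape))


def _band_mask(T: int, tr: float, band_hz: tuple[float, float]) -> np.ndarray:
    low, high = band_hz
    nyquist = 1.0 / (2.0 * tr)
    if not 0 < low < high < nyquist:
        raise ValueError(
            f"band {band_hz} must lie strictly inside (0, {nyquist:.4g}) Hz for TR {tr} s"
        )
    freqs = np.fft.rfftfreq(T, d=tr)
    return (freqs >= low) & (freqs <= high)


def bandpass(bold: Bold4D, band_hz: tuple[float, float] = (0.01, 0.08)) -> Bold4D:
    """Ideal DFT band-pass: keep coefficients with low <= f <= high, zero the
    rest (DC included), inverse-transform to a real series."""
    T = bold.n_volumes
    if T < 20:
        raise ValueError(f"band-pass needs T >= 20, got {T}")
    keep = _band_mask(T, bold.grid.tr_seconds, band_hz)
    flat = bold.data.reshape(T, -1)
    spec = np.fft.rfft(flat, axis=0)
    spec[~keep] = 0
    out = np.fft.irfft(spec, n=T, axis=0)
    return bold.with_data(out.reshape(bold.data.shape))


def preprocess_subject(
    bold: Bold4D,
    motion: np.ndarray,
    atlas: LabelVolume,
    config: PreprocConfig = PreprocConfig(),
) -> Bold4D:
    """Run the fixed-order per-subject pipeline.

    Order: discard -> smooth -> nuisance regression -> band-pass. Tissue
    means are computed from the smoothed, discard-truncated series.
    """
    bold, motion = discard_initial_volumes(bold, config.n_discard, motion)
    bold = smooth_fwhm(bold, config.fwhm_mm)
    design = build_nuisance_design(motion, bold, atlas)
    bold = residualize(bold, design)
    return bandpass(bold, config.band_hz)
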