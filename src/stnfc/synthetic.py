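"""Synthetic multi-site resting-state cohort generator.

The generator emulates the statistical structure the analysis assumes —
not the biophysics of BOLD. Each subject receives band-limited
(0.01-0.08 Hz) unit-variance latent signals: one per hemispheric seed
(sharing a common component so the interhemispheric coupling is
controllable and may drift with age), and one per effect region. An
effect region with target coupling rho carries ``rho * s(t) +
sqrt(1 - rho^2) * eps(t)`` against its seed latent, with rho a linear
function of the subject's age. On top of the signal every voxel receives
i.i.d. Gaussian noise, a site-specific mean offset, a linear drift, a
motion-coupled component (a linear mixture of the subject's six simulated
realignment parameters, so the motion regressors can remove it exactly),
and brain-wide white-matter/CSF components that the tissue-mean
regressors can remove.

All randomness derives from ``rng_seed``; per-subject streams are keyed
by a stable hash of the subject id, so cohorts are bit-reproducible and
order-independent.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .core import (
    ROLE_CSF,
    ROLE_GM,
    ROLE_SEED_LEFT,
    ROLE_SEED_RIGHT,
    ROLE_WM,
    Bold4D,
    LabelVolume,
    VolumeGrid,
)

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "sample_phenotypes",
    "build_atlas",
    "simulate_subject",
    "simulate_cohort",
]

_SEED_LABELS = {ROLE_SEED_LEFT: 1, ROLE_SEED_RIGHT: 2}
_TISSUE_LABELS = {ROLE_GM: 3, ROLE_WM: 4, ROLE_CSF: 5}
_EFFECT_LABEL_START = 10

# Stream tags for deriving independent RNG streams from the root seed.
_STREAM_PHENOTYPES = 101
_STREAM_SUBJECT = 202


@dataclass(frozen=True)
class EffectSpec:
    """A region whose seed coupling varies linearly with age.

    ``baseline_r`` is the target Pearson coupling at the cohort mean age;
    ``age_slope_per_year`` its change per year of age. ``side`` selects
    which seed latent the region couples to: ``left_seed``, ``right_seed``
    or ``both`` (the bilateral composite).
    """

    region_label: int
    baseline_r: float
    age_slope_per_year: float = 0.0
    side: str = "both"

    def __post_init__(self) -> None:
        if not -1 < self.baseline_r < 1:
            raise ValueError(f"baseline_r must be in (-1,1), got {self.baseline_r}")
        if self.side not in ("left_seed", "right_seed", "both"):
            raise ValueError(f"unknown side {self.side!r}")

    def rho_at(self, age: float, mean_age: float) -> float:
        return self.baseline_r + self.age_slope_per_year * (age - mean_age)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generating parameters.

    Defaults emulate the study conditions of the multi-site aging sample
    the pipeline targets: 361 adults aged 18-85 (34.5% female) from 3
    sites, 250 volumes at TR 2.2 s on a ~3 mm isotropic grid, with planted
    couplings of the magnitudes reported for insula-, sensorimotor- and
    precuneus-like regions (e.g. r ~ 0.13 declining by 0.002/yr). The
    16^3 grid is a desk-scale stand-in for a whole-brain field of view.
    """

    n_subjects: int = 361
    age_range_years: tuple[float, float] = (18.0, 85.0)
    fraction_female: float = 0.345
    n_sites: int = 3
    grid: VolumeGrid = field(
        default_factory=lambda: VolumeGrid.isotropic((16, 16, 16), 3.1, 2.2)
    )
    n_volumes: int = 250
    effects: tuple[EffectSpec, ...] = (
        EffectSpec(region_label=10, baseline_r=0.13, age_slope_per_year=-0.002, side="both"),
        EffectSpec(region_label=11, baseline_r=0.08, age_slope_per_year=+0.002, side="both"),
        EffectSpec(region_label=12, baseline_r=-0.05, age_slope_per_year=+0.002, side="both"),
    )
    noise_sd: float = 1.0
    motion_sd: float = 0.5
    tissue_signal_sd: float = 1.0
    drift_amplitude: float = 1.0
    interhemispheric_r: float = 0.43
    interhemispheric_slope_per_year: float = 0.0013
    band_hz: tuple[float, float] = (0.01, 0.08)
    n_discard: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_subjects < 2 * self.n_sites:
            raise ValueError("need n_subjects >= 2 * n_sites")
        if self.n_volumes <= self.n_discard + 20:
            raise ValueError("n_volumes must exceed discard count + 20")
        if not 0 <= self.fraction_female <= 1:
            raise ValueError("fraction_female must be in [0,1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.age_range_years
        if not lo < hi:
            raise ValueError("age range must be increasing")
        mid_ages = (lo, hi)
        for eff in self.effects:
            for age in mid_ages:
                rho = eff.rho_at(age, (lo + hi) / 2)
                if abs(rho) >= 1:
                    raise ValueError(
                        f"effect {eff.region_label}: |rho|={abs(rho):.3f} >= 1 at age {age}"
                    )


@dataclass
class SyntheticCohort:
    """In-memory cohort: phenotypes, shared atlas, per-subject data, truth."""

    config: SimulationConfig
    phenotypes: pd.DataFrame
    atlas: LabelVolume
    bolds: dict[str, Bold4D]
    motions: dict[str, np.ndarray]
    ground_truth: pd.DataFrame  # one row per (subject, effect region)
    mean_age: float


def _subject_rng(root_seed: int, subject_id: str) -> np.random.Generator:
    digest = hashlib.sha256(subject_id.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(
        np.random.SeedSequence([int(root_seed), _STREAM_SUBJECT, key])
    )


def sample_phenotypes(config: SimulationConfig) -> pd.DataFrame:
    """Draw the cohort roster: uniform ages, Bernoulli sexes, round-robin sites."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.rng_seed), _STREAM_PHENOTYPES])
    )
    n = config.n_subjects
    lo, hi = config.age_range_years
    ids = [f"sub-{i + 1:04d}" for i in range(n)]
    ages = rng.uniform(lo, hi, size=n)
    sexes = np.where(rng.random(n) < config.fraction_female, "F", "M")
    sites = [f"site_{i % config.n_sites + 1}" for i in range(n)]
    df = pd.DataFrame(
        {
            "subject_id": ids,
            "age_years": np.round(ages, 4),
            "sex": sexes,
            "site": sites,
            "bold_path": [f"{s}_bold.nii.gz" for s in ids],
            "motion_path": [f"{s}_motion.txt" for s in ids],
        }
    )
    df["sex"] = pd.Categorical(df["sex"], categories=["F", "M"])
    df["site"] = pd.Categorical(df["site"])
    return df


def _place_block(
    occupied: np.ndarray, size: tuple[int, int, int], clearance: int
) -> tuple[slice, slice, slice]:
    """First lexicographic anchor where a block fits with the given clearance."""
    from scipy import ndimage

    shape = occupied.shape
    if clearance > 0 and occupied.any():
        forbidden = ndimage.binary_dilation(occupied, iterations=clearance)
    else:
        forbidden = occupied
    for x in range(shape[0] - size[0] + 1):
        for y in range(shape[1] - size[1] + 1):
            for z in range(shape[2] - size[2] + 1):
                sl = (slice(x, x + size[0]), slice(y, y + size[1]), slice(z, z + size[2]))
                if not forbidden[sl].any():
                    return sl
    raise ValueError(f"cannot place a {size} block disjointly on grid {shape}")


def build_atlas(config: SimulationConfig) -> LabelVolume:
    """Deterministic label volume: cuboid seeds, WM/CSF compartments and one
    3x3x3 block per effect region; everything else is GM background.

    Cuboids (rather than anatomical shapes) give exact voxel counts for
    cluster-extent tests.
    """
    shape = config.grid.shape
    labels = np.zeros(shape, dtype=np.int64)
    occupied = np.zeros(shape, dtype=bool)
    legend: dict[int, str] = {}

    def place(label: int, role: str, size: tuple[int, int, int]) -> None:
        sl = _place_block(occupied, size, clearance=2)
        labels[sl] = label
        occupied[sl] = True
        legend[label] = role

    place(_SEED_LABELS[ROLE_SEED_LEFT], ROLE_SEED_LEFT, (2, 2, 2))
    place(_SEED_LABELS[ROLE_SEED_RIGHT], ROLE_SEED_RIGHT, (2, 2, 2))
    place(_TISSUE_LABELS[ROLE_WM], ROLE_WM, (3, 3, 3))
    place(_TISSUE_LABELS[ROLE_CSF], ROLE_CSF, (3, 3, 3))
    for k, eff in enumerate(config.effects):
        place(eff.region_label, f"effect_{k + 1}", (3, 3, 3))

    labels[~occupied] = _TISSUE_LABELS[ROLE_GM]
    legend[_TISSUE_LABELS[ROLE_GM]] = ROLE_GM
    return LabelVolume(grid=config.grid, labels=labels, legend=legend)


def _band_limited_latents(
    rng: np.random.Generator, n_series: int, T: int, tr: float, band: tuple[float, float]
) -> np.ndarray:
    """(n_series, T) unit-variance Gaussian latents band-limited to ``band``."""
    white = rng.standard_normal((n_series, T))
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(white, axis=1)
    spec[:, ~keep] = 0
    out = np.fft.irfft(spec, n=T, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _simulate_motion(rng: np.random.Generator, T: int, motion_sd: float) -> np.ndarray:
    """Six slow AR(1) realignment-parameter series (3 mm, 3 rad)."""
    phi = 0.95
    innov = rng.standard_normal((T, 6))
    m = np.empty((T, 6))
    m[0] = innov[0]
    for t in range(1, T):
        m[t] = phi * m[t - 1] + np.sqrt(1 - phi**2) * innov[t]
    scale = np.array([1.0, 1.0, 1.0, 0.01, 0.01, 0.01]) * motion_sd
    return m * scale


def simulate_subject(
    row: pd.Series,
    atlas: LabelVolume,
    config: SimulationConfig,
    mean_age: float,
) -> tuple[Bold4D, np.ndarray, dict[str, float]]:
    """One subject's BOLD series and motion table, plus realized couplings.

    Deterministic given ``config.rng_seed`` and the subject id.
    """
    rng = _subject_rng(config.rng_seed, str(row["subject_id"]))
    T = config.n_volumes
    tr = config.grid.tr_seconds
    age = float(row["age_years"])

    # Seed latents: left/right share a common component g so that
    # corr(s_L, s_R) = rho_lr, which may drift with age.
    rho_lr = float(
        np.clip(
            config.interhemispheric_r
            + config.interhemispheric_slope_per_year * (age - mean_age),
            -0.999,
            0.999,
        )
    )
    if rho_lr < 0:
        raise ValueError("interhemispheric coupling must be non-negative in this model")
    g, u_left, u_right = _band_limited_latents(rng, 3, T, tr, config.band_hz)
    s_left = np.sqrt(rho_lr) * g + np.sqrt(1 - rho_lr) * u_left
    s_right = np.sqrt(rho_lr) * g + np.sqrt(1 - rho_lr) * u_right
    denom = np.sqrt(2 * (1 + rho_lr))
    s_both = (s_left + s_right) / denom

    seed_series = {"left_seed": s_left, "right_seed": s_right, "both": s_both}

    truth: dict[str, float] = {"interhemispheric_r": rho_lr}
    region_signal: dict[int, np.ndarray] = {}
    eps = _band_limited_latents(rng, len(config.effects), T, tr, config.band_hz)
    for k, eff in enumerate(config.effects):
        rho = eff.rho_at(age, mean_age)
        if abs(rho) >= 1:
            raise ValueError(
                f"effect region {eff.region_label}: |rho|={abs(rho):.3f} >= 1 "
                f"for subject {row['subject_id']} (age {age:.1f})"
            )
        region_signal[eff.region_label] = rho * seed_series[eff.side] + np.sqrt(1 - rho**2) * eps[k]
        truth[f"rho_effect_{k + 1}"] = rho

    motion = _simulate_motion(rng, T, config.motion_sd)
    wm_sig, csf_sig = _band_limited_latents(rng, 2, T, tr, config.band_hz)

    shape = config.grid.shape
    n_vox = int(np.prod(shape))
    flat_labels = atlas.labels.ravel()

    data = rng.standard_normal((T, n_vox)) * config.noise_sd
    data += 100.0  # baseline intensity

    # Structured signals per compartment.
    data[:, flat_labels == _SEED_LABELS[ROLE_SEED_LEFT]] += s_left[:, None]
    data[:, flat_labels == _SEED_LABELS[ROLE_SEED_RIGHT]] += s_right[:, None]
    for label, sig in region_signal.items():
        data[:, flat_labels == label] += sig[:, None]
    data[:, flat_labels == _TISSUE_LABELS[ROLE_WM]] += config.tissue_signal_sd * wm_sig[:, None]
    data[:, flat_labels == _TISSUE_LABELS[ROLE_CSF]] += config.tissue_signal_sd * csf_sig[:, None]

    # Brain-wide contamination the nuisance regressors are built to remove:
    # tissue-wide WM/CSF components, linear drift, site offset, motion mixing.
    data += 0.5 * config.tissue_signal_sd * (wm_sig + csf_sig)[:, None]
    drift = np.linspace(-1.0, 1.0, T)
    data += config.drift_amplitude * drift[:, None]
    site_no = int(str(row["site"]).rsplit("_", 1)[-1])
    data += 5.0 * site_no

    if config.motion_sd > 0:
        m_std = motion - motion.mean(axis=0)
        sd = m_std.std(axis=0)
        sd[sd == 0] = 1.0
        m_std = m_std / sd
        loadings = rng.standard_normal((6, n_vox)) / np.sqrt(6)
        data += config.motion_sd * (m_std @ loadings)

    bold = Bold4D(
        grid=config.grid,
        data=data.reshape(T, *shape),
        subject_id=str(row["subject_id"]),
    )
    return bold, motion, truth


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticCohort:
    """Generate a full cohort; optionally write all files to ``out_dir``.

    Writes (when ``out_dir`` is given): one BOLD NIfTI and one motion
    table per subject, the shared atlas with its legend sidecar, and the
    phenotype TSV. The returned manifest holds the exact generating
    couplings per subject for recovery tests.
    """
    phenotypes = sample_phenotypes(config)
    mean_age = float(phenotypes["age_years"].mean())
    atlas = build_atlas(config)

    bolds: dict[str, Bold4D] = {}
    motions: dict[str, np.ndarray] = {}
    truth_rows = []
    for _, row in phenotypes.iterrows():
        bold, motion, truth = simulate_subject(row, atlas, config, mean_age)
        sid = str(row["subject_id"])
        bolds[sid] = bold
        motions[sid] = motion
        truth_rows.append({"subject_id": sid, "age_years": row["age_years"], **truth})
    ground_truth = pd.DataFrame(truth_rows)

    cohort = SyntheticCohort(
        config=config,
        phenotypes=phenotypes,
        atlas=atlas,
        bolds=bolds,
        motions=motions,
        ground_truth=ground_truth,
        mean_age=mean_age,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_phenotypes(phenotypes, out / "phenotypes.tsv")
        io.write_label_volume(atlas, out / "atlas.nii.gz")
        ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False, float_format="%.8f")
        for _, row in phenotypes.iterrows():
            sid = str(row["subject_id"])
            io.write_bold(bolds[sid], out / str(row["bold_path"]))
            io.write_motion(motions[sid], out / str(row["motion_path"]))
    return cohort


def null_config(**overrides) -> SimulationConfig:
    """A cohort with baseline couplings but no age effect anywhere.

    Used for family-wise-error calibration: effect regions keep their
    baseline coupling (so the FC main effect is real) while every age
    slope, including the interhemispheric one, is zero.
    """
    base = SimulationConfig()
    effects = tuple(replace(e, age_slope_per_year=0.0) for e in base.effects)
    cfg = replace(base, effects=effects, interhemispheric_slope_per_year=0.0)
    return replace(cfg, **overrides) if overrides else cfg
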