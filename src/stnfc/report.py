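"""Per-cluster aging statistics and the supplementary hemispheric analyses.

For each surviving cluster the cohort is split at the age median into
equally sized younger/older halves, mean couplings are reported per half
(mean Fisher-Z over cluster voxels, back-transformed to r), the young-old
difference is tested with a Welch two-sample t on the subject-level Z
values, and the age association is summarized by a Spearman rank
correlation over all subjects. Clusters are only retained if the mean
coupling exceeds |r| > 0.1 in at least one age half (a small effect by
Cohen's convention).

Sign convention for the difference t: young minus old, so a coupling that
declines with age gives a positive t and one that strengthens with age a
negative t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Bold4D, LabelVolume
from .group import (
    ClusterSet,
    ContrastPair,
    GroupDesign,
    StatMap,
    fit_glm_tmaps,
    permutation_cluster_fwe,
    stack_fcmaps,
)
from .seed_fc import FCMap, seed_series

__all__ = [
    "SplitHalf",
    "ClusterStats",
    "ClusterReport",
    "split_half",
    "cluster_subject_fc",
    "cluster_stats",
    "effect_filter",
    "hemispheric_analysis",
    "interhemispheric_fc_vs_age",
]


@dataclass(frozen=True)
class SplitHalf:
    """Age-median split into equal halves; middle subject dropped when N odd."""

    young_ids: tuple[str, ...]
    old_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.young_ids) & set(self.old_ids):
            raise ValueError("young and old halves overlap")
        if len(self.young_ids) != len(self.old_ids):
            raise ValueError("halves must have equal size")


@dataclass
class ClusterStats:
    cluster_id: int
    mean_r_young: float
    mean_r_old: float
    t_delta_r: float
    spearman_age: float

    @property
    def passes_effect_filter(self) -> bool:
        return abs(self.mean_r_young) > 0.1 or abs(self.mean_r_old) > 0.1


def split_half(phenotypes: pd.DataFrame) -> SplitHalf:
    """Sort by age (ties broken by subject id) and split at the median.

    The lower floor(N/2) subjects form the younger half, the upper
    floor(N/2) the older half; for odd N the median subject is excluded.
    """
    n = len(phenotypes)
    if n < 4:
        raise ValueError(f"need at least 4 subjects to split, got {n}")
    order = phenotypes.sort_values(
        ["age_years", "subject_id"], kind="mergesort"
    )["subject_id"].astype(str).tolist()
    half = n // 2
    young = tuple(order[:half])
    old = tuple(order[-half:])
    return SplitHalf(young_ids=young, old_ids=old)


def cluster_subject_fc(
    cluster_mask: np.ndarray, zmaps: list[FCMap]
) -> np.ndarray:
    """Per-subject cluster coupling: mean Fisher-Z over cluster voxels,
    back-transformed to r = tanh(mean z)."""
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if not cluster_mask.any():
        raise ValueError("cluster is empty")
    mean_z = np.array([m.z_values[cluster_mask].mean() for m in zmaps])
    return np.tanh(mean_z)


def _cluster_mean_z(cluster_mask: np.ndarray, zmaps: list[FCMap]) -> np.ndarray:
    return np.array([m.z_values[np.asarray(cluster_mask, bool)].mean() for m in zmaps])


def _spearman(values: np.ndarray, ages: np.ndarray) -> float:
    """Spearman rank correlation; 0.0 for a constant input (undefined)."""
    if np.ptp(values) == 0 or np.ptp(ages) == 0:
        return 0.0
    rho, _ = stats.spearmanr(values, ages)
    return float(rho)


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Welch (unequal-variance) two-sample t for mean(a) - mean(b)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se = np.sqrt(va / len(a) + vb / len(b))
    if se == 0:
        return 0.0 if a.mean() == b.mean() else np.sign(a.mean() - b.mean()) * np.inf
    return float((a.mean() - b.mean()) / se)


def cluster_stats(
    cluster_mask: np.ndarray,
    zmaps: list[FCMap],
    phenotypes: pd.DataFrame,
    split: SplitHalf,
    cluster_id: int = 1,
) -> ClusterStats:
    """Table-style aging statistics for one cluster.

    ``zmaps`` must be in phenotype row order. The difference t is Welch's
    t on subject-level mean-Z, young minus old; the Spearman correlation
    uses all subjects (average ranks for ties).
    """
    ids = phenotypes["subject_id"].astype(str).tolist()
    if len(ids) != len(zmaps):
        raise ValueError("zmaps must align with phenotype rows")
    mean_z = _cluster_mean_z(cluster_mask, zmaps)
    by_id = dict(zip(ids, mean_z))
    young = np.array([by_id[s] for s in split.young_ids])
    old = np.array([by_id[s] for s in split.old_ids])
    rho = _spearman(mean_z, phenotypes["age_years"].to_numpy(float))
    return ClusterStats(
        cluster_id=cluster_id,
        mean_r_young=float(np.tanh(young.mean())),
        mean_r_old=float(np.tanh(old.mean())),
        t_delta_r=welch_t(young, old),
        spearman_age=rho,
    )


def effect_filter(cs: ClusterStats, threshold: float = 0.1) -> bool:
    """Keep a cluster iff |mean r| exceeds ``threshold`` in either age half
    (strict inequality)."""
    return abs(cs.mean_r_young) > threshold or abs(cs.mean_r_old) > threshold


@dataclass
class ClusterReport:
    """Finalized clusters of one contrast, ready for the output table."""

    clusters: ClusterSet
    stats: list[ClusterStats]
    subject_fc: dict[int, np.ndarray]  # cluster_id -> per-subject r
    effect_threshold: float = 0.1

    def to_rows(self) -> list[dict]:
        cs = self.clusters
        if cs.p_fwe is None:
            raise ValueError("clusters are not finalized: p_fwe missing")
        if len(self.stats) != cs.n_clusters:
            raise ValueError("clusters are not finalized: statistics missing")
        rows = []
        for k in range(cs.n_clusters):
            st = self.stats[k]
            world = cs.grid.voxel_to_world(cs.peak_index[k])
            rows.append(
                {
                    "cluster_id": k + 1,
                    "contrast": cs.contrast,
                    "n_voxels": int(cs.sizes[k]),
                    "peak_x_mm": float(world[0]),
                    "peak_y_mm": float(world[1]),
                    "peak_z_mm": float(world[2]),
                    "peak_t": float(cs.peak_t[k]),
                    "p_fwe": float(cs.p_fwe[k]),
                    "mean_r_young": st.mean_r_young,
                    "mean_r_old": st.mean_r_old,
                    "t_delta_r": st.t_delta_r,
                    "spearman_age": st.spearman_age,
                }
            )
        return rows

    def filtered_rows(self, significant_only: bool = True) -> list[dict]:
        rows = self.to_rows()
        keep = []
        for k, row in enumerate(rows):
            if significant_only and not self.clusters.significant[k]:
                continue
            if not effect_filter(self.stats[k], self.effect_threshold):
                continue
            keep.append(row)
        return keep


def finalize_clusters(
    clusters: ClusterSet,
    zmaps: list[FCMap],
    phenotypes: pd.DataFrame,
    effect_threshold: float = 0.1,
) -> ClusterReport:
    """Attach per-cluster aging statistics to a corrected ClusterSet."""
    split = split_half(phenotypes)
    stats_list = []
    subject_fc = {}
    for k in range(clusters.n_clusters):
        mask = clusters.cluster_mask(k + 1)
        stats_list.append(cluster_stats(mask, zmaps, phenotypes, split, cluster_id=k + 1))
        subject_fc[k + 1] = cluster_subject_fc(mask, zmaps)
    return ClusterReport(
        clusters=clusters, stats=stats_list, subject_fc=subject_fc,
        effect_threshold=effect_threshold,
    )


def _difference_maps(zmaps_left: list[FCMap], zmaps_right: list[FCMap]) -> list[FCMap]:
    if len(zmaps_left) != len(zmaps_right):
        raise ValueError("left/right map stacks differ in length")
    out = []
    for ml, mr in zip(zmaps_left, zmaps_right):
        if ml.subject_id != mr.subject_id:
            raise ValueError(
                f"subject mismatch between map stacks: {ml.subject_id} vs {mr.subject_id}"
            )
        if not ml.grid.same_space(mr.grid):
            raise ValueError("left/right maps on different grids")
        mask = ml.mask & mr.mask
        d = np.where(mask, ml.z_values - mr.z_values, 0.0)
        out.append(
            FCMap(grid=ml.grid, z_values=d, mask=mask,
                  subject_id=ml.subject_id, seed_source="left_minus_right")
        )
    return out


def hemispheric_analysis(
    zmaps_left: list[FCMap],
    zmaps_right: list[FCMap],
    design: GroupDesign,
    pairs: list[ContrastPair] | None = None,
    n_perm: int = 1000,
    forming_p: float = 0.001,
    cluster_alpha: float = 0.05,
    connectivity: int = 26,
    rng_seed: int | None = None,
) -> tuple[dict[str, StatMap], dict[str, ClusterSet]]:
    """Paired hemispheric-difference inference on D = Z_left - Z_right.

    The same covariate model is fit to the per-subject difference maps;
    the intercept tests D != 0 in the requested direction and the age
    column tests age modulation of the difference, corrected as in the
    main analysis.
    """
    from .group import CONTRAST_PAIRS

    dmaps = _difference_maps(zmaps_left, zmaps_right)
    stacked = stack_fcmaps(dmaps)
    tmaps = fit_glm_tmaps(stacked, design)
    if pairs is None:
        pairs = list(CONTRAST_PAIRS.values())
    clusters = {}
    for pair in pairs:
        clusters[pair.name] = permutation_cluster_fwe(
            stacked, design, pair, n_perm=n_perm, forming_p=forming_p,
            cluster_alpha=cluster_alpha, connectivity=connectivity,
            rng_seed=rng_seed,
        )
    return tmaps, clusters


def interhemispheric_fc_vs_age(
    bolds: list[Bold4D],
    atlas: LabelVolume,
    phenotypes: pd.DataFrame,
) -> tuple[np.ndarray, float, float]:
    """Coupling between the two hemispheric seeds versus age.

    Per subject, r between the left and right seed eigenvariates
    (computed on preprocessed series, in phenotype order); returns the
    per-subject r, the Spearman correlation of Fisher-Z with age over all
    subjects, and the Welch t (young minus old) between split halves.
    """
    if len(bolds) != len(phenotypes):
        raise ValueError("bolds must align with phenotype rows")
    r_vals = []
    for bold in bolds:
        left = seed_series(bold, atlas, "left")
        right = seed_series(bold, atlas, "right")
        r = float(np.corrcoef(left.values, right.values)[0, 1])
        r_vals.append(r)
    r_vals = np.asarray(r_vals)
    z_vals = np.arctanh(np.clip(r_vals, -1 + 1e-7, 1 - 1e-7))
    rho = _spearman(z_vals, phenotypes["age_years"].to_numpy(float))
    split = split_half(phenotypes)
    ids = phenotypes["subject_id"].astype(str).tolist()
    by_id = dict(zip(ids, z_vals))
    t = welch_t(
        np.array([by_id[s] for s in split.young_ids]),
        np.array([by_id[s] for s in split.old_ids]),
    )
    return r_vals, float(rho), t
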