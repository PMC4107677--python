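"""Group-level inference on stacks of Fisher-Z connectivity maps.

Per voxel an ordinary-least-squares model with intercept, centered age,
centered sex and sum-to-zero site codes is fit across subjects; with all
covariates centered the intercept estimates the covariate-adjusted grand
mean (the FC main effect). Age effects are tested in conjunction with the
main effect: a voxel enters a cluster only if both one-sided t tests pass
the cluster-forming threshold in the requested directions.

Cluster-level family-wise error is controlled by a Freedman-Lane
permutation of the age covariate: residuals of the reduced model (all
columns but age) are permuted, the full model is refit, and the maximum
conjunction-cluster size is recorded per permutation. The main-effect
pass-mask is held fixed across permutations — permuting age cannot break
the main effect, whose role here is only to restrict where age effects
may be declared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import VolumeGrid
from .seed_fc import FCMap

__all__ = [
    "GroupDesign",
    "ContrastPair",
    "CONTRAST_PAIRS",
    "StatMap",
    "ClusterSet",
    "build_group_design",
    "stack_fcmaps",
    "fit_glm_tmaps",
    "conjunction_clusters",
    "permutation_cluster_fwe",
]

T_CAP = 1e6  # t magnitude reported for zero-residual (interpolating) fits


@dataclass
class GroupDesign:
    """Subjects x covariates matrix for the group GLM."""

    matrix: np.ndarray
    column_names: list[str]
    df_residual: int

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> int:
        return self.column_names.index(name)


@dataclass(frozen=True)
class ContrastPair:
    """A conjunction of one FC main-effect direction with one age direction.

    ``main_sign`` +1 tests positive FC (t_intercept above threshold),
    -1 negative FC; ``age_sign`` +1 tests age-related increase, -1
    decrease.
    """

    name: str
    main_sign: int
    age_sign: int


CONTRAST_PAIRS: dict[str, ContrastPair] = {
    "pos_fc_age_decrease": ContrastPair("pos_fc_age_decrease", +1, -1),
    "pos_fc_age_increase": ContrastPair("pos_fc_age_increase", +1, +1),
    "neg_fc_age_decrease": ContrastPair("neg_fc_age_decrease", -1, +1),
    "neg_fc_age_increase": ContrastPair("neg_fc_age_increase", -1, -1),
}
# Note the sign conventions for negative FC: "age-related decrease of
# anticorrelation" means the (negative) adjusted mean moves toward zero,
# i.e. the age slope is positive (neg_fc_age_decrease -> age_sign +1).


@dataclass
class StatMap:
    grid: VolumeGrid
    t_values: np.ndarray
    mask: np.ndarray
    df: int
    contrast: str


@dataclass
class ClusterSet:
    """Labeled suprathreshold components with optional corrected p-values."""

    grid: VolumeGrid
    labels: np.ndarray  # X,Y,Z int, 0 = background, clusters 1..K
    sizes: np.ndarray  # (K,) voxel counts
    peak_index: np.ndarray  # (K, 3) voxel index of the age-effect peak
    peak_t: np.ndarray  # (K,) age t at the peak
    connectivity: int
    forming_p: float
    contrast: str
    p_fwe: np.ndarray | None = None
    cluster_alpha: float = 0.05
    liberal_alpha: float = 0.1
    n_perm: int | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def significant(self) -> np.ndarray:
        if self.p_fwe is None:
            raise ValueError("p_fwe not computed; run permutation correction first")
        return self.p_fwe < self.cluster_alpha

    @property
    def liberal(self) -> np.ndarray:
        if self.p_fwe is None:
            raise ValueError("p_fwe not computed; run permutation correction first")
        return self.p_fwe < self.liberal_alpha

    def cluster_mask(self, cluster_id: int) -> np.ndarray:
        return self.labels == cluster_id


def build_group_design(phenotypes: pd.DataFrame) -> GroupDesign:
    """Intercept + centered age + centered sex (+-0.5) + centered sum-to-zero
    site codes. Zero-variance covariates are dropped with a warning;
    collinear columns raise."""
    n = len(phenotypes)
    cols = [np.ones(n)]
    names = ["intercept"]

    age = phenotypes["age_years"].to_numpy(dtype=float)
    cols.append(age - age.mean())
    names.append("age")

    sex = pd.Categorical(phenotypes["sex"])
    if len(sex.categories) == 2:
        sx = np.where(sex.codes == 0, -0.5, 0.5)
        cols.append(sx - sx.mean())
        names.append("sex")
    else:
        warnings.warn("single-sex cohort: dropping sex covariate", stacklevel=2)

    site = pd.Categorical(phenotypes["site"])
    levels = list(site.categories)
    if len(levels) >= 2:
        for j, lev in enumerate(levels[:-1]):
            col = np.where(site.codes == j, 1.0, np.where(site.codes == len(levels) - 1, -1.0, 0.0))
            cols.append(col - col.mean())
            names.append(f"site_{lev}")
    else:
        warnings.warn("single-site cohort: dropping site covariate", stacklevel=2)

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"group design is collinear among columns {names}")
    if n <= X.shape[1]:
        raise ValueError(f"need more subjects ({n}) than design columns ({X.shape[1]})")
    return GroupDesign(matrix=X, column_names=names, df_residual=n - rank)


def stack_fcmaps(zmaps: list[FCMap]) -> tuple[np.ndarray, np.ndarray, VolumeGrid]:
    """Stack subject maps to (N, V) over the intersection of subject masks."""
    if not zmaps:
        raise ValueError("no maps to stack")
    grid = zmaps[0].grid
    for m in zmaps:
        if not m.grid.same_space(grid):
            raise ValueError("all FC maps must share one grid")
    mask = np.logical_and.reduce([m.mask for m in zmaps])
    if not mask.any():
        raise ValueError("intersection of subject masks is empty")
    Y = np.stack([m.z_values[mask] for m in zmaps])
    return Y, mask, grid


@dataclass
class _GLMFit:
    """Precomputed pieces for fast repeated fits with one design."""

    X: np.ndarray
    pinv: np.ndarray
    xtx_inv_diag: np.ndarray
    df: int

    @classmethod
    def from_design(cls, design: GroupDesign) -> "_GLMFit":
        X = design.matrix
        pinv = np.linalg.pinv(X)
        xtx_inv = np.linalg.inv(X.T @ X)
        return cls(X=X, pinv=pinv, xtx_inv_diag=np.diag(xtx_inv).copy(), df=design.df_residual)

    def t_stats(self, Y: np.ndarray, col: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-column OLS beta and t for one design column; Y is (N, V)."""
        beta = self.pinv @ Y
        resid = Y - self.X @ beta
        rss = np.einsum("ij,ij->j", resid, resid)
        sigma2 = rss / self.df
        se = np.sqrt(sigma2 * self.xtx_inv_diag[col])
        b = beta[col]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b / se
        t[se == 0] = np.sign(b[se == 0]) * T_CAP
        np.clip(t, -T_CAP, T_CAP, out=t)
        return b, t


def fit_glm_tmaps(
    zmaps: list[FCMap] | tuple[np.ndarray, np.ndarray, VolumeGrid],
    design: GroupDesign,
) -> dict[str, StatMap]:
    """Per-voxel OLS t-maps for the intercept (FC main effect) and age.

    ``zmaps`` may be a list of per-subject maps (in design row order) or a
    pre-stacked ``(Y, mask, grid)`` triple.
    """
    if isinstance(zmaps, list):
        Y, mask, grid = stack_fcmaps(zmaps)
    else:
        Y, mask, grid = zmaps
    if Y.shape[0] != design.n_subjects:
        raise ValueError(
            f"{Y.shape[0]} subject maps but design has {design.n_subjects} rows"
        )
    fit = _GLMFit.from_design(design)
    out: dict[str, StatMap] = {}
    for name in ("intercept", "age"):
        _, t = fit.t_stats(Y, design.column(name))
        vol = np.zeros(grid.shape)
        vol[mask] = t
        out[name] = StatMap(grid=grid, t_values=vol, mask=mask, df=fit.df, contrast=name)
    return out


def _structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order[connectivity])


def _label_clusters(pass_mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, np.ndarray]:
    labels, k = ndimage.label(pass_mask, structure=_structure(connectivity))
    if k == 0:
        return labels, np.zeros(0, dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return labels, sizes


def forming_threshold(forming_p: float, df: int) -> float:
    """One-sided cluster-forming t threshold: inverse Student-t of 1 - p."""
    if not 0 < forming_p < 1:
        raise ValueError("forming_p must be in (0,1)")
    return float(stats.t.isf(forming_p, df))


def conjunction_clusters(
    main: StatMap,
    age: StatMap,
    pair: ContrastPair,
    forming_p: float = 0.001,
    connectivity: int = 26,
) -> ClusterSet:
    """Label connected components of voxels passing BOTH one-sided tests.

    A voxel passes iff sign*t exceeds the forming threshold on the main
    map and on the age map, each in the pair's direction.
    """
    if not main.grid.same_space(age.grid):
        raise ValueError("main and age maps are on different grids")
    t_crit = forming_threshold(forming_p, age.df)
    pass_mask = (
        main.mask
        & age.mask
        & (pair.main_sign * main.t_values > t_crit)
        & (pair.age_sign * age.t_values > t_crit)
    )
    labels, sizes = _label_clusters(pass_mask, connectivity)
    peaks = np.zeros((len(sizes), 3), dtype=int)
    peak_t = np.zeros(len(sizes))
    signed_age = pair.age_sign * age.t_values
    for k in range(len(sizes)):
        idx = np.argwhere(labels == k + 1)
        best = idx[np.argmax(signed_age[tuple(idx.T)])]
        peaks[k] = best
        peak_t[k] = age.t_values[tuple(best)]
    return ClusterSet(
        grid=main.grid, labels=labels, sizes=sizes,
        peak_index=peaks, peak_t=peak_t,
        connectivity=connectivity, forming_p=forming_p, contrast=pair.name,
    )


def permutation_cluster_fwe(
    zmaps: list[FCMap] | tuple[np.ndarray, np.ndarray, VolumeGrid],
    design: GroupDesign,
    pair: ContrastPair,
    n_perm: int = 1000,
    forming_p: float = 0.001,
    cluster_alpha: float = 0.05,
    liberal_alpha: float = 0.1,
    connectivity: int = 26,
    rng_seed: int | None = None,
) -> ClusterSet:
    """Cluster-level FWE-corrected conjunction inference.

    Freedman-Lane scheme on the age covariate: the reduced model (all
    columns except age) is fit once; per permutation its residuals are
    row-shuffled, the full model refit, the age t-map recomputed over the
    FIXED observed main-effect pass-mask, and the maximum conjunction
    cluster size recorded. ``p_fwe = (1 + #{perm max >= size}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError(f"need n_perm >= 100, got {n_perm}")
    if rng_seed is None:
        raise ValueError("rng_seed is required for reproducible permutation inference")
    if isinstance(zmaps, list):
        Y, mask, grid = stack_fcmaps(zmaps)
    else:
        Y, mask, grid = zmaps
    if Y.shape[0] != design.n_subjects:
        raise ValueError("subject count mismatch between maps and design")

    fit = _GLMFit.from_design(design)
    age_col = design.column("age")
    _, t_main = fit.t_stats(Y, design.column("intercept"))
    _, t_age = fit.t_stats(Y, age_col)
    t_crit = forming_threshold(forming_p, fit.df)

    main_map = StatMap(grid=grid, t_values=_embed(t_main, mask, grid), mask=mask,
                       df=fit.df, contrast="intercept")
    age_map = StatMap(grid=grid, t_values=_embed(t_age, mask, grid), mask=mask,
                      df=fit.df, contrast="age")
    observed = conjunction_clusters(main_map, age_map, pair, forming_p, connectivity)
    observed.cluster_alpha = cluster_alpha
    observed.liberal_alpha = liberal_alpha
    observed.n_perm = n_perm

    # Permutation t-maps are only needed on the fixed main-effect pass-mask.
    main_pass_flat = pair.main_sign * t_main > t_crit
    main_pass_vol = np.zeros(grid.shape, dtype=bool)
    main_pass_vol[mask] = main_pass_flat

    max_sizes = np.zeros(n_perm, dtype=int)
    if main_pass_flat.any():
        Xr = np.delete(fit.X, age_col, axis=1)
        Qr, _ = np.linalg.qr(Xr)
        Ys = Y[:, main_pass_flat]
        fitted_r = Qr @ (Qr.T @ Ys)
        resid_r = Ys - fitted_r
        sub_fit = _GLMFit(X=fit.X, pinv=fit.pinv, xtx_inv_diag=fit.xtx_inv_diag, df=fit.df)
        rng = np.random.default_rng(rng_seed)
        n = Y.shape[0]
        pass_vol = np.zeros(grid.shape, dtype=bool)
        sub_index = np.argwhere(main_pass_vol)
        sub_index_t = tuple(sub_index.T)
        for p in range(n_perm):
            perm = rng.permutation(n)
            Yp = fitted_r + resid_r[perm]
            _, t_perm = sub_fit.t_stats(Yp, age_col)
            passing = pair.age_sign * t_perm > t_crit
            pass_vol[:] = False
            pass_vol[sub_index_t] = passing
            _, sizes = _label_clusters(pass_vol, connectivity)
            max_sizes[p] = sizes.max() if sizes.size else 0

    if observed.n_clusters:
        exceed = (max_sizes[None, :] >= observed.sizes[:, None]).sum(axis=1)
        observed.p_fwe = (1.0 + exceed) / (1.0 + n_perm)
    else:
        observed.p_fwe = np.zeros(0)
    return observed


def _embed(flat: np.ndarray, mask: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    vol = np.zeros(grid.shape)
    vol[mask] = flat
    return vol
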