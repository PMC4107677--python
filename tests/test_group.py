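import numpy as np
import pytest

from stnfc.core import VolumeGrid
from stnfc.group import (
    CONTRAST_PAIRS,
    StatMap,
    T_CAP,
    _label_clusters,
    build_group_design,
    conjunction_clusters,
    fit_glm_tmaps,
    forming_threshold,
    permutation_cluster_fwe,
    stack_fcmaps,
)

from conftest import make_fcmap, make_phenotypes


@pytest.fixture(scope="module")
def grid2():
    return VolumeGrid.isotropic((2, 2, 2), 3.1, 2.2)


def _random_phenotypes(n, rng, n_sites=3):
    ages = rng.uniform(18, 85, n)
    sexes = ["F" if rng.random() < 0.4 else "M" for _ in range(n)]
    sites = [f"site_{i % n_sites + 1}" for i in range(n)]
    return make_phenotypes(ages, sexes, sites)


class TestGroupDesign:
    def test_361_subjects_three_sites(self):
        rng = np.random.default_rng(0)
        design = build_group_design(_random_phenotypes(361, rng))
        assert design.matrix.shape == (361, 5)
        assert design.df_residual == 356
        assert design.column_names == ["intercept", "age", "sex",
                                       "site_site_1", "site_site_2"]

    def test_age_column_centered(self):
        rng = np.random.default_rng(1)
        design = build_group_design(_random_phenotypes(40, rng))
        assert abs(design.matrix[:, design.column("age")].sum()) < 1e-10

    def test_degenerate_covariates_dropped_with_warning(self):
        df = make_phenotypes([20, 30, 40, 50, 60, 70],
                             sexes=["M"] * 6, sites=["site_1"] * 6)
        with pytest.warns(UserWarning):
            design = build_group_design(df)
        assert design.column_names == ["intercept", "age"]
        assert design.matrix.shape == (6, 2)

    def test_collinear_columns_rejected(self):
        # sex perfectly aliased with site -> sex and site codes collinear
        df = make_phenotypes(
            [20, 30, 40, 50, 60, 70],
            sexes=["M", "M", "M", "F", "F", "F"],
            sites=["site_1", "site_1", "site_1", "site_2", "site_2", "site_2"],
        )
        with pytest.raises(ValueError, match="collinear"):
            build_group_design(df)


class TestFitGLM:
    def test_noise_free_age_effect_recovered_exactly(self, grid2):
        rng = np.random.default_rng(2)
        pheno = _random_phenotypes(30, rng)
        ages = pheno["age_years"].to_numpy(float)
        age_c = ages - ages.mean()
        maps = [make_fcmap(grid2, np.full(grid2.shape, 0.3 + 0.002 * a),
                           subject_id=s)
                for a, s in zip(age_c, pheno["subject_id"])]
        design = build_group_design(pheno)
        tmaps = fit_glm_tmaps(maps, design)
        # exact interpolation: residuals 0 -> t capped
        assert (np.abs(tmaps["age"].t_values[tmaps["age"].mask]) == T_CAP).all()
        Y, _, _ = stack_fcmaps(maps)
        beta = np.linalg.lstsq(design.matrix, Y, rcond=None)[0]
        assert beta[design.column("age")][0] == pytest.approx(0.002, abs=1e-10)
        assert beta[design.column("intercept")][0] == pytest.approx(0.3, abs=1e-10)

    def test_matches_normal_equations_oracle(self, grid2):
        rng = np.random.default_rng(3)
        pheno = _random_phenotypes(40, rng)
        maps = [make_fcmap(grid2, rng.standard_normal(grid2.shape), subject_id=s)
                for s in pheno["subject_id"]]
        design = build_group_design(pheno)
        tmaps = fit_glm_tmaps(maps, design)
        X = design.matrix
        y = np.array([m.z_values[0, 1, 1] for m in maps])
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / design.df_residual
        for name in ("intercept", "age"):
            j = design.column(name)
            t_oracle = beta[j] / np.sqrt(sigma2 * xtx_inv[j, j])
            assert tmaps[name].t_values[0, 1, 1] == pytest.approx(t_oracle, abs=1e-8)

    def test_subject_order_invariance(self, grid2):
        rng = np.random.default_rng(4)
        pheno = _random_phenotypes(25, rng)
        maps = [make_fcmap(grid2, rng.standard_normal(grid2.shape), subject_id=s)
                for s in pheno["subject_id"]]
        t1 = fit_glm_tmaps(maps, build_group_design(pheno))
        perm = rng.permutation(25)
        pheno2 = pheno.iloc[perm].reset_index(drop=True)
        maps2 = [maps[i] for i in perm]
        t2 = fit_glm_tmaps(maps2, build_group_design(pheno2))
        np.testing.assert_allclose(t1["age"].t_values, t2["age"].t_values, atol=1e-8)

    def test_too_few_subjects_rejected(self):
        # 4 subjects cannot support intercept + age + sex + site
        df = make_phenotypes([20, 30, 40, 50], sexes=["M", "F", "F", "M"],
                             sites=["site_1", "site_2", "site_1", "site_2"])
        with pytest.raises(ValueError, match="subjects"):
            build_group_design(df)


def test_forming_threshold_matches_numerical_integration_oracle():
    """Inverse Student-t via an independent quadrature + root-finding oracle."""
    import math

    from scipy.integrate import quad
    from scipy.optimize import brentq

    df, p = 356, 0.001

    log_c = math.lgamma((df + 1) / 2) - math.lgamma(df / 2) - 0.5 * math.log(df * math.pi)

    def pdf(x):
        return math.exp(log_c - (df + 1) / 2 * math.log1p(x * x / df))

    def sf(x):
        return quad(pdf, x, np.inf)[0]

    oracle = brentq(lambda x: sf(x) - p, 0.1, 50.0, xtol=1e-12)
    assert forming_threshold(p, df) == pytest.approx(oracle, abs=1e-9)


def _flood_fill_components(mask, connectivity):
    """Brute-force BFS connected components oracle."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if (connectivity == 6 and order == 1) or \
                   (connectivity == 18 and order <= 2) or connectivity == 26:
                    offsets.append((dx, dy, dz))
    remaining = {tuple(v) for v in np.argwhere(mask)}
    comps = []
    while remaining:
        start = remaining.pop()
        queue, comp = [start], {start}
        while queue:
            x, y, z = queue.pop()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


@pytest.mark.parametrize("connectivity", [6, 18, 26])
@pytest.mark.parametrize("density,seed", [(0.2, 0), (0.4, 1), (0.6, 2)])
def test_cluster_labeling_matches_bfs_oracle(connectivity, density, seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((8, 8, 8)) < density
    labels, sizes = _label_clusters(mask, connectivity)
    got = set()
    for k in range(len(sizes)):
        got.add(frozenset(tuple(v) for v in np.argwhere(labels == k + 1)))
    assert got == _flood_fill_components(mask, connectivity)
    assert sorted(sizes) == sorted(len(c) for c in got)


def test_connectivity_monotone_refinement():
    rng = np.random.default_rng(5)
    mask = rng.random((8, 8, 8)) < 0.35
    l6, s6 = _label_clusters(mask, 6)
    l26, s26 = _label_clusters(mask, 26)
    # every 6-connectivity cluster lies inside exactly one 26-connectivity cluster
    for k in range(len(s6)):
        parents = np.unique(l26[l6 == k + 1])
        assert len(parents) == 1 and parents[0] != 0


class TestConjunction:
    def _statmap(self, grid, t_vol, df=40):
        return StatMap(grid=grid, t_values=np.asarray(t_vol, float),
                       mask=np.ones(grid.shape, bool), df=df, contrast="x")

    def test_null_age_map_gives_empty_set(self):
        grid = VolumeGrid.isotropic((6, 6, 6), 3.1, 2.2)
        main = self._statmap(grid, np.full(grid.shape, 10.0))
        age = self._statmap(grid, np.zeros(grid.shape))
        cs = conjunction_clusters(main, age, CONTRAST_PAIRS["pos_fc_age_decrease"])
        assert cs.n_clusters == 0

    def test_single_passing_voxel(self):
        grid = VolumeGrid.isotropic((6, 6, 6), 3.1, 2.2)
        tm = np.zeros(grid.shape)
        ta = np.zeros(grid.shape)
        tm[2, 3, 4] = 10.0
        ta[2, 3, 4] = -10.0
        cs = conjunction_clusters(self._statmap(grid, tm), self._statmap(grid, ta),
                                  CONTRAST_PAIRS["pos_fc_age_decrease"])
        assert cs.n_clusters == 1
        assert cs.sizes.tolist() == [1]
        assert cs.peak_index[0].tolist() == [2, 3, 4]
        assert cs.peak_t[0] == -10.0

    def test_conjunction_subset_of_marginal_pass_sets(self):
        rng = np.random.default_rng(6)
        grid = VolumeGrid.isotropic((8, 8, 8), 3.1, 2.2)
        tm = rng.standard_normal(grid.shape) * 4
        ta = rng.standard_normal(grid.shape) * 4
        pair = CONTRAST_PAIRS["pos_fc_age_decrease"]
        cs = conjunction_clusters(self._statmap(grid, tm), self._statmap(grid, ta),
                                  pair, forming_p=0.01)
        t_crit = forming_threshold(0.01, 40)
        conj = cs.labels > 0
        assert (conj <= (tm > t_crit)).all()
        assert (conj <= (-ta > t_crit)).all()

    def test_mismatched_grids_rejected(self):
        g1 = VolumeGrid.isotropic((6, 6, 6), 3.1, 2.2)
        g2 = VolumeGrid.isotropic((5, 5, 5), 3.1, 2.2)
        with pytest.raises(ValueError, match="grid"):
            conjunction_clusters(
                self._statmap(g1, np.zeros(g1.shape)),
                self._statmap(g2, np.zeros(g2.shape)),
                CONTRAST_PAIRS["pos_fc_age_decrease"],
            )


class TestPermutationFWE:
    def _planted_stack(self, n=30, seed=7):
        """Maps with a strong planted age decline in a 3x3x3 block."""
        rng = np.random.default_rng(seed)
        grid = VolumeGrid.isotropic((8, 8, 8), 3.1, 2.2)
        pheno = _random_phenotypes(n, rng)
        ages = pheno["age_years"].to_numpy(float)
        age_c = ages - ages.mean()
        maps = []
        for a, s in zip(age_c, pheno["subject_id"]):
            vol = rng.standard_normal(grid.shape) * 0.05
            vol[2:5, 2:5, 2:5] += 0.5 - 0.01 * a
            maps.append(make_fcmap(grid, vol, subject_id=s))
        return maps, build_group_design(pheno)

    def test_dominant_cluster_reaches_p_floor(self):
        maps, design = self._planted_stack()
        cs = permutation_cluster_fwe(
            maps, design, CONTRAST_PAIRS["pos_fc_age_decrease"],
            n_perm=200, rng_seed=1,
        )
        assert cs.n_clusters >= 1
        assert cs.p_fwe.min() == pytest.approx(1 / 201)
        assert bool(cs.significant[np.argmin(cs.p_fwe)])

    def test_p_values_bounded(self):
        maps, design = self._planted_stack(seed=8)
        cs = permutation_cluster_fwe(
            maps, design, CONTRAST_PAIRS["pos_fc_age_decrease"],
            n_perm=150, rng_seed=2,
        )
        if cs.n_clusters:
            assert (cs.p_fwe >= 1 / 151).all()
            assert (cs.p_fwe <= 1.0).all()

    def test_too_few_permutations_rejected(self):
        maps, design = self._planted_stack()
        with pytest.raises(ValueError, match="n_perm"):
            permutation_cluster_fwe(maps, design,
                                    CONTRAST_PAIRS["pos_fc_age_decrease"],
                                    n_perm=50, rng_seed=1)

    def test_seed_required(self):
        maps, design = self._planted_stack()
        with pytest.raises(ValueError, match="rng_seed"):
            permutation_cluster_fwe(maps, design,
                                    CONTRAST_PAIRS["pos_fc_age_decrease"],
                                    n_perm=200)

    def test_planted_z_space_decline_detected_reliably(self):
        """An age decline of 0.004 z-units/yr in a 27-voxel region (N=80,
        subject-level z noise at the band-limited sampling floor ~0.117)
        is detected with p_fwe < 0.05 in at least 90% of replicates."""
        grid = VolumeGrid.isotropic((16, 16, 16), 3.1, 2.2)
        pair = CONTRAST_PAIRS["pos_fc_age_decrease"]
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            pheno = _random_phenotypes(80, rng)
            age_c = pheno["age_years"].to_numpy(float)
            age_c = age_c - age_c.mean()
            maps = []
            for a, s in zip(age_c, pheno["subject_id"]):
                vol = rng.standard_normal(grid.shape) * 0.117
                vol[6:9, 6:9, 6:9] += 0.13 - 0.004 * a
                maps.append(make_fcmap(grid, vol, subject_id=s))
            cs = permutation_cluster_fwe(
                maps, build_group_design(pheno), pair,
                n_perm=200, rng_seed=2000 + rep,
            )
            region = np.zeros(grid.shape, bool)
            region[6:9, 6:9, 6:9] = True
            hits += any(
                cs.p_fwe[k] < 0.05 and (cs.cluster_mask(k + 1) & region).any()
                for k in range(cs.n_clusters)
            )
        assert hits / n_rep >= 0.9

    def test_deterministic_given_seed(self):
        maps, design = self._planted_stack()
        kw = dict(n_perm=120, rng_seed=5)
        a = permutation_cluster_fwe(maps, design,
                                    CONTRAST_PAIRS["pos_fc_age_decrease"], **kw)
        b = permutation_cluster_fwe(maps, design,
                                    CONTRAST_PAIRS["pos_fc_age_decrease"], **kw)
        np.testing.assert_array_equal(a.p_fwe, b.p_fwe)
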