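"""Cohort-level calibration studies: empirical FWE and detection power.

These run the full pipeline (simulation -> preprocessing -> seed FC ->
group GLM -> permutation cluster FWE) over many independent synthetic
cohorts and summarize how often clusters are declared significant. They
are the package's own check that its cluster-level inference keeps its
nominal error rate, and that a planted aging effect of a realistic
magnitude is recovered.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .core import VolumeGrid
from .pipeline import RunConfig, analyze_cohort
from .synthetic import EffectSpec, SimulationConfig, null_config, simulate_cohort

__all__ = ["null_cohort_fwe", "planted_decline_power"]

AGE_DECREASE = "pos_fc_age_decrease"


def _derived_seed(base_seed: int, stream: int, index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(stream), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def null_cohort_fwe(
    n_cohorts: int = 200,
    base_seed: int = 1,
    n_subjects: int = 40,
    n_volumes: int = 120,
    n_perm: int = 500,
    cluster_alpha: float = 0.05,
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    progress: bool = False,
) -> tuple[float, int]:
    """Fraction of independent null cohorts with any significant cluster.

    Each cohort keeps its baseline seed couplings (so the FC main effect
    is real) but has no age effect anywhere; the age-decrease conjunction
    is then tested at the default thresholds (voxel p<0.001, cluster
    p<0.05, 26-connectivity). Returns ``(fraction, n_cohorts)``.
    """
    n_with_sig = 0
    for i in range(n_cohorts):
        cfg = null_config(
            n_subjects=n_subjects,
            n_volumes=n_volumes,
            grid=VolumeGrid.isotropic(grid_shape, 3.1, 2.2),
            rng_seed=_derived_seed(base_seed, 11, i),
        )
        cohort = simulate_cohort(cfg)
        run = RunConfig(
            n_perm=n_perm, cluster_alpha=cluster_alpha,
            contrasts=(AGE_DECREASE,),
            rng_seed=_derived_seed(base_seed, 12, i),
        )
        analysis = analyze_cohort(cohort, config=run)
        cs = analysis.clusters[AGE_DECREASE]
        if cs.n_clusters and (cs.p_fwe < cluster_alpha).any():
            n_with_sig += 1
        if progress and (i + 1) % 20 == 0:
            print(f"  null cohort {i + 1}/{n_cohorts}: "
                  f"running FWE {n_with_sig / (i + 1):.3f}", flush=True)
    return n_with_sig / n_cohorts, n_cohorts


def planted_decline_power(
    n_replicates: int = 50,
    base_seed: int = 2,
    n_subjects: int = 80,
    baseline_r: float = 0.13,
    slope_per_year: float = -0.002,
    n_perm: int = 500,
    cluster_alpha: float = 0.05,
    progress: bool = False,
) -> tuple[float, int]:
    """Detection rate for a planted linear age decline of seed coupling.

    A 27-voxel region carries coupling ``baseline_r`` at the cohort mean
    age declining by ``slope_per_year``; a replicate counts as detected
    when a significant cluster of the positive-FC age-decrease
    conjunction overlaps the planted region. Returns ``(power,
    n_replicates)``.
    """
    base = SimulationConfig()
    hits = 0
    for i in range(n_replicates):
        cfg = replace(
            base,
            n_subjects=n_subjects,
            effects=(EffectSpec(region_label=10, baseline_r=baseline_r,
                                age_slope_per_year=slope_per_year, side="both"),),
            rng_seed=_derived_seed(base_seed, 21, i),
        )
        cohort = simulate_cohort(cfg)
        run = RunConfig(
            n_perm=n_perm, cluster_alpha=cluster_alpha,
            contrasts=(AGE_DECREASE,),
            rng_seed=_derived_seed(base_seed, 22, i),
        )
        analysis = analyze_cohort(cohort, config=run)
        cs = analysis.clusters[AGE_DECREASE]
        region = cohort.atlas.mask("effect_1")
        detected = any(
            cs.p_fwe[k] < cluster_alpha and (cs.cluster_mask(k + 1) & region).any()
            for k in range(cs.n_clusters)
        )
        hits += detected
        if progress and (i + 1) % 10 == 0:
            print(f"  replicate {i + 1}/{n_replicates}: "
                  f"running power {hits / (i + 1):.2f}", flush=True)
    return hits / n_replicates, n_replicates
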