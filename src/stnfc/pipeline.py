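"""End-to-end orchestration: simulate -> preprocess -> FC -> group -> report.

A run is fully determined by its :class:`RunConfig` and root RNG seed.
Per-stage random streams are derived from the root seed by stable integer
tags, so subject-level work is order-independent and two runs with the
same config produce byte-identical cluster tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .core import Bold4D, LabelVolume
from .group import (
    CONTRAST_PAIRS,
    ClusterSet,
    build_group_design,
    fit_glm_tmaps,
    permutation_cluster_fwe,
    stack_fcmaps,
)
from .preprocess import PreprocConfig, preprocess_subject
from .report import ClusterReport, finalize_clusters
from .seed_fc import FCMap, fc_zmap, seed_series
from .synthetic import SimulationConfig, SyntheticCohort, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "analyze_cohort", "CohortAnalysis"]

log = logging.getLogger("stnfc")

_STREAM_PERMUTATION = 303


@dataclass
class RunConfig:
    """Everything needed to reproduce a full run."""

    cohort_dir: str = "cohort"
    output_dir: str = "run"
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    seed_source: str = "bilateral"
    contrasts: tuple[str, ...] = tuple(CONTRAST_PAIRS)
    forming_p: float = 0.001
    cluster_alpha: float = 0.05
    liberal_alpha: float = 0.1
    n_perm: int = 1000
    connectivity: int = 26
    effect_threshold: float = 0.1
    rng_seed: int = 0
    save_zmaps: bool = False
    write_scatter: bool = True

    def __post_init__(self) -> None:
        for name in ("forming_p", "cluster_alpha", "liberal_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        unknown = set(self.contrasts) - set(CONTRAST_PAIRS)
        if unknown:
            raise ValueError(f"unknown contrast name(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "preproc" in raw:
            pp = raw["preproc"]
            if "band_hz" in pp:
                pp["band_hz"] = tuple(pp["band_hz"])
            raw["preproc"] = PreprocConfig(**pp)
        if "contrasts" in raw:
            raw["contrasts"] = tuple(raw["contrasts"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["preproc"]["band_hz"] = list(d["preproc"]["band_hz"])
        d["contrasts"] = list(d["contrasts"])
        return d


def _perm_seed(root_seed: int, contrast: str) -> int:
    digest = hashlib.sha256(contrast.encode()).digest()
    mix = np.random.SeedSequence(
        [int(root_seed), _STREAM_PERMUTATION, int.from_bytes(digest[:4], "big")]
    )
    return int(mix.generate_state(1)[0] % (2**31))


@dataclass
class CohortAnalysis:
    """All per-stage products of one analyzed cohort."""

    zmaps: list[FCMap]
    design: object
    tmaps: dict
    clusters: dict[str, ClusterSet]
    reports: dict[str, ClusterReport]


def analyze_cohort(
    cohort: SyntheticCohort | None = None,
    *,
    phenotypes: pd.DataFrame | None = None,
    atlas: LabelVolume | None = None,
    bolds: dict[str, Bold4D] | None = None,
    motions: dict[str, np.ndarray] | None = None,
    config: RunConfig = RunConfig(),
) -> CohortAnalysis:
    """Analyze an in-memory cohort end to end (no disk I/O).

    Accepts either a :class:`SyntheticCohort` or the four components
    explicitly. Subject order follows the phenotype table.
    """
    if cohort is not None:
        phenotypes, atlas = cohort.phenotypes, cohort.atlas
        bolds, motions = cohort.bolds, cohort.motions
    if phenotypes is None or atlas is None or bolds is None or motions is None:
        raise ValueError("provide a cohort or all of phenotypes/atlas/bolds/motions")

    gm_mask = atlas.gm_analysis_mask()
    zmaps: list[FCMap] = []
    for _, row in phenotypes.iterrows():
        sid = str(row["subject_id"])
        clean = preprocess_subject(bolds[sid], motions[sid], atlas, config.preproc)
        seed = seed_series(clean, atlas, config.seed_source)
        zmaps.append(fc_zmap(clean, seed, gm_mask))
        log.info("fc %s: seed=%s voxels=%d", sid, config.seed_source, seed.n_voxels_used)

    design = build_group_design(phenotypes)
    stacked = stack_fcmaps(zmaps)
    tmaps = fit_glm_tmaps(stacked, design)

    clusters: dict[str, ClusterSet] = {}
    reports: dict[str, ClusterReport] = {}
    for name in config.contrasts:
        cs = permutation_cluster_fwe(
            stacked, design, CONTRAST_PAIRS[name],
            n_perm=config.n_perm, forming_p=config.forming_p,
            cluster_alpha=config.cluster_alpha, liberal_alpha=config.liberal_alpha,
            connectivity=config.connectivity,
            rng_seed=_perm_seed(config.rng_seed, name),
        )
        clusters[name] = cs
        reports[name] = finalize_clusters(cs, zmaps, phenotypes, config.effect_threshold)
        log.info("group %s: %d cluster(s)", name, cs.n_clusters)
    return CohortAnalysis(zmaps=zmaps, design=design, tmaps=tmaps,
                          clusters=clusters, reports=reports)


def _combined_table(reports: dict[str, ClusterReport]) -> pd.DataFrame:
    rows: list[dict] = []
    for name in sorted(reports):
        rows.extend(reports[name].to_rows())
    return pd.DataFrame(rows, columns=io.CLUSTER_TABLE_COLUMNS)


def run_pipeline(
    config: RunConfig, simulate: SimulationConfig | None = None
) -> Path:
    """Run the full pipeline against a cohort directory.

    If ``simulate`` is given the cohort is generated (and written) first.
    Writes t-map NIfTIs, the cluster TSV and a manifest to
    ``config.output_dir``; identical config and seed give a byte-identical
    cluster table.
    """
    cohort_dir = Path(config.cohort_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort: SyntheticCohort | None = None
    if simulate is not None:
        log.info("simulate: %d subjects -> %s", simulate.n_subjects, cohort_dir)
        cohort = simulate_cohort(simulate, out_dir=cohort_dir)

    phenotypes = io.read_phenotypes(cohort_dir / "phenotypes.tsv")
    atlas = io.read_label_volume(cohort_dir / "atlas.nii.gz")
    bolds: dict[str, Bold4D] = {}
    motions: dict[str, np.ndarray] = {}
    for _, row in phenotypes.iterrows():
        sid = str(row["subject_id"])
        try:
            bolds[sid] = io.read_bold(cohort_dir / str(row["bold_path"]))
            motions[sid] = io.read_motion(cohort_dir / str(row["motion_path"]))
        except Exception as err:
            raise RuntimeError(f"stage=load subject={sid}: {err}") from err

    analysis = analyze_cohort(
        phenotypes=phenotypes, atlas=atlas, bolds=bolds, motions=motions,
        config=config,
    )

    if config.save_zmaps:
        for m in analysis.zmaps:
            io.write_zmap(m.grid, m.z_values,
                          out_dir / f"{m.subject_id}_{m.seed_source}_zmap.nii.gz")
    for name, sm in analysis.tmaps.items():
        io.write_zmap(sm.grid, sm.t_values, out_dir / f"tmap_{name}.nii.gz")

    table_path = out_dir / "clusters.tsv"
    table = _combined_table(analysis.reports)
    table.to_csv(table_path, sep="\t", index=False, float_format="%.6f")

    if config.write_scatter:
        ages = phenotypes["age_years"].to_numpy(dtype=float)
        for name, rep in analysis.reports.items():
            for k, r_vals in rep.subject_fc.items():
                scatter = pd.DataFrame(
                    {"subject_id": phenotypes["subject_id"],
                     "age_years": ages, "fc_r": r_vals}
                )
                scatter.to_csv(out_dir / f"scatter_{name}_cluster{k}.tsv",
                               sep="\t", index=False, float_format="%.6f")

    manifest = {
        "config": config.to_dict(),
        "rng_seed": config.rng_seed,
        "n_subjects": len(phenotypes),
        "contrast_cluster_counts": {
            name: int(cs.n_clusters) for name, cs in analysis.clusters.items()
        },
        "cluster_table_sha256": hashlib.sha256(table_path.read_bytes()).hexdigest(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("run complete: %s", out_dir)
    return out_dir
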