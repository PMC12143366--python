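"""End-to-end orchestration: simulate (or load) -> filter/normalize -> DE ->
pairwise parallelism -> PCA geometry -> level comparisons + jackknife ->
gene-set parallelism, with every intermediate written as TSV/JSON and a single
machine-readable run summary."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare as cmp
from . import gosets
from .de import de_tables_for_level, filter_by_cpm, normalize_log_cpm
from .geometry import evolution_vector, level_angles, run_pca
from .io import (
    read_counts,
    read_design,
    read_gene_sets,
    write_counts,
    write_design,
    write_detable,
    write_gene_sets,
)
from .model import CountMatrix, ExparallelError, SampleDesign, check_join
from .parallelism import pairwise_frame, pairwise_table, pairwise_values
from .simulate import LevelDesign, SimulationConfig, default_level_designs, simulate_study

log = logging.getLogger(__name__)

DEFAULT_PLANES = (("PC2", "PC3"), ("PC3", "PC4"))


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    counts_path: str | None = None  # when set (with design_path), load instead of simulating
    design_path: str | None = None
    genesets_path: str | None = None
    fdr_threshold: float = 0.05
    cpm_threshold: float = 1.0
    planes: tuple[tuple[str, str], ...] = DEFAULT_PLANES
    jackknife_k: int = 3
    go_min_size: int = 5
    go_min_genes: int = 5
    go_fdr_threshold: float = 0.05
    direction_concordant: bool = False

    def validate(self) -> None:
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ExparallelError("fdr_threshold must lie in (0, 1]")
        if not 0.0 < self.go_fdr_threshold <= 1.0:
            raise ExparallelError("go_fdr_threshold must lie in (0, 1]")
        if self.cpm_threshold <= 0:
            raise ExparallelError("cpm_threshold must be positive")
        if self.jackknife_k < 2:
            raise ExparallelError("jackknife_k must be >= 2")
        if (self.counts_path is None) != (self.design_path is None):
            raise ExparallelError("counts_path and design_path must be given together")
        self.simulation.validate()

    @property
    def seed(self) -> int:
        return self.simulation.seed

    def with_seed(self, seed: int) -> "RunConfig":
        sim = dataclasses.replace(self.simulation, seed=seed)
        return dataclasses.replace(self, simulation=sim)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim_data = dict(data.pop("simulation", {}))
        lds = sim_data.pop("level_designs", None)
        if lds is not None:
            sim_data["level_designs"] = tuple(LevelDesign(**ld) for ld in lds)
        else:
            sim_data.setdefault("level_designs", default_level_designs())
        for key in ("libsize_range", "set_size_range"):
            if key in sim_data:
                sim_data[key] = tuple(sim_data[key])
        sim = SimulationConfig(**sim_data)
        if "planes" in data:
            data["planes"] = tuple(tuple(p) for p in data["planes"])
        cfg = cls(simulation=sim, **data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _acquire_inputs(config: RunConfig):
    if config.counts_path is not None:
        counts = read_counts(config.counts_path)
        design = read_design(config.design_path)
        check_join(counts, design)
        sets = (
            read_gene_sets(config.genesets_path, universe=counts.gene_ids)
            if config.genesets_path
            else None
        )
        return counts, design, sets, None
    counts, design, sets, truth = simulate_study(config.simulation)
    return counts, design, sets, truth


def _gene_level_stage(config: RunConfig, counts: CountMatrix, design: SampleDesign):
    detables = {}
    pairwise = {}
    for level in design.levels():
        detables[level] = de_tables_for_level(
            counts, design, level, cpm_threshold=config.cpm_threshold
        )
        pairwise[level] = pairwise_table(
            detables[level],
            fdr_threshold=config.fdr_threshold,
            direction_concordant=config.direction_concordant,
        )
        log.info(
            "level %s: %d units, %d pairwise records",
            level,
            len(detables[level]),
            len(pairwise[level]),
        )
    return detables, pairwise


def _geometry_stage(config: RunConfig, counts: CountMatrix, design: SampleDesign):
    filtered = filter_by_cpm(counts, config.cpm_threshold)
    norm = normalize_log_cpm(filtered)
    pca = run_pca(norm)
    vectors = []
    angles = []
    for plane in config.planes:
        if any(c not in pca.scores.columns for c in plane):
            log.warning("plane %s not available at rank %d; skipped", plane, pca.scores.shape[1])
            continue
        vecs = {
            level: evolution_vector(pca, design, level, plane) for level in design.levels()
        }
        vectors.extend(vecs.values())
        angles.extend(level_angles(vecs))
    return pca, vectors, angles


def _comparison_stage(config: RunConfig, values_by_stat: dict[str, dict[str, list[float]]]):
    comparisons = []
    jackknives = []
    for stat, values_by_level in values_by_stat.items():
        if any(
            lv not in values_by_level or not values_by_level[lv]
            for lv in ("within_population", "between_populations", "between_species")
        ):
            log.warning("statistic %s lacks a level; comparisons skipped", stat)
            continue
        comparisons.extend(cmp.compare_levels(values_by_level, statistic=stat))
    return comparisons, jackknives


def run_study(config: RunConfig, outdir) -> dict:
    """Execute every stage and write all artifacts under ``outdir``.  Returns
    (and writes) the JSON run summary.  Identical config => identical outputs."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("stage simulate/load")
    counts, design, sets, truth = _acquire_inputs(config)
    write_counts(counts, outdir / "counts.tsv")
    write_design(design, outdir / "design.tsv")
    if sets is not None:
        write_gene_sets(sets, outdir / "genesets.tsv")
    if truth is not None:
        (outdir / "truth.json").write_text(json.dumps(truth.to_json_dict(), sort_keys=True))

    log.info("stage differential expression + pairwise parallelism")
    detables, pairwise = _gene_level_stage(config, counts, design)
    de_dir = outdir / "de"
    de_dir.mkdir(exist_ok=True)
    for level, tables in detables.items():
        for de in tables:
            write_detable(de, de_dir / f"{de.unit_id.replace(':', '_')}.tsv")
    for level, records in pairwise.items():
        pairwise_frame(records).to_csv(outdir / f"parallelism_{level}.tsv", sep="\t", index=False)

    log.info("stage geometry")
    pca, vectors, angles = _geometry_stage(config, counts, design)
    pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame(
        [
            {
                "level": v.level,
                "plane": "-".join(v.plane),
                "origin_x": v.origin[0],
                "origin_y": v.origin[1],
                "tip_x": v.tip[0],
                "tip_y": v.tip[1],
                "slope": np.nan if v.slope is None else v.slope,
                "vertical": v.vertical,
            }
            for v in vectors
        ]
    ).to_csv(outdir / "vectors.tsv", sep="\t", index=False)
    pd.DataFrame(angles).to_csv(outdir / "angles.tsv", sep="\t", index=False)

    log.info("stage gene-set parallelism")
    go_summary: dict = {}
    go_pair_values: dict[str, dict[str, list[float]]] = {"jaccard_go": {}, "rho_go": {}}
    term_frames_by_level: dict[str, list[pd.DataFrame]] = {}
    go_dir = outdir / "go"
    go_dir.mkdir(exist_ok=True)
    if sets is not None:
        for level, tables in detables.items():
            universe = tables[0].gene_ids
            level_sets = sets.restrict_to_universe(universe)
            enriched_by_unit = {}
            for de in tables:
                enr = gosets.fisher_enrichment(
                    de.significant_genes(config.fdr_threshold),
                    universe,
                    level_sets,
                    min_size=config.go_min_size,
                    fdr_threshold=config.go_fdr_threshold,
                )
                enr.to_csv(
                    go_dir / f"enrichment_{de.unit_id.replace(':', '_')}.tsv",
                    sep="\t",
                    index_label="set_id",
                )
                enriched_by_unit[de.unit_id] = gosets.enriched_sets(enr)
            tested_sets = {
                sid
                for sid in level_sets
                if len(level_sets.members(sid)) >= config.go_min_size
            }
            jac_vals, frames = [], []
            from itertools import combinations as _comb

            from .parallelism import jaccard as _jaccard

            rho_vals = []
            for de_a, de_b in _comb(tables, 2):
                jac_vals.append(
                    _jaccard(enriched_by_unit[de_a.unit_id], enriched_by_unit[de_b.unit_id])
                )
                frame = gosets.per_term_correlation(
                    de_a, de_b, level_sets, min_genes=config.go_min_genes
                )
                frames.append(frame)
                rho_vals.append(float(frame["rho"].mean()))
            go_pair_values["jaccard_go"][level] = jac_vals
            go_pair_values["rho_go"][level] = rho_vals
            term_frames_by_level[level] = frames
            gosets.mean_term_correlation(frames).to_csv(
                go_dir / f"term_correlation_{level}.tsv", sep="\t", index_label="set_id"
            )
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1013904223]))
        go_summary = gosets.summarize_term_distributions(term_frames_by_level, rng=rng)
        (go_dir / "summary.json").write_text(json.dumps(go_summary, sort_keys=True))

    log.info("stage level comparisons")
    values_by_stat: dict[str, dict[str, list[float]]] = {
        "jaccard_genes": {
            lv: [r.jaccard for r in recs] for lv, recs in pairwise.items()
        },
        "rho_genes": {
            lv: [r.rho for r in recs if r.rho is not None] for lv, recs in pairwise.items()
        },
    }
    for stat, by_level in go_pair_values.items():
        if by_level:
            values_by_stat[stat] = by_level
    comparisons, _ = _comparison_stage(config, values_by_stat)
    comp_frame = pd.DataFrame(
        [
            {
                "statistic": c.statistic,
                "level_a": c.level_pair[0],
                "level_b": c.level_pair[1],
                "n_obs": c.n_obs,
                "reference": c.reference,
                "wilcoxon_p": c.wilcoxon_p,
                "p_bonferroni": c.p_bonferroni,
                "consistent": c.consistent,
            }
            for c in comparisons
        ]
    )
    comp_frame.to_csv(outdir / "level_comparisons.tsv", sep="\t", index=False)

    log.info("stage jackknife")
    jackknives = []
    within = pairwise.get("within_population", [])
    if within and len({u for r in within for u in (r.unit_a, r.unit_b)}) > config.jackknife_k:
        for stat_name, attr in (("jaccard_genes", "jaccard"), ("rho_genes", "rho")):
            pv = pairwise_values(within, attr)
            for ref_name in ("between_populations", "between_species"):
                ref_vals = values_by_stat[stat_name].get(ref_name)
                if not ref_vals:
                    continue
                jackknives.append(
                    cmp.jackknife_parallelism(
                        pv,
                        config.jackknife_k,
                        float(np.mean(ref_vals)),
                        statistic=f"{stat_name}_vs_{ref_name}",
                    )
                )
    (outdir / "jackknife.json").write_text(
        json.dumps([j.to_json_dict() for j in jackknives], sort_keys=True)
    )

    summary = {
        "seed": config.seed,
        "fdr_threshold": config.fdr_threshold,
        "n_pairs": {lv: len(recs) for lv, recs in pairwise.items()},
        "n_significant_genes": {
            lv: {de.unit_id: len(de.significant_genes(config.fdr_threshold)) for de in tables}
            for lv, tables in detables.items()
        },
        "mean_jaccard": {
            lv: float(np.mean(vals)) for lv, vals in values_by_stat["jaccard_genes"].items()
        },
        "mean_rho": {
            lv: float(np.mean(vals)) for lv, vals in values_by_stat["rho_genes"].items()
        },
        "variance_explained": pca.variance_explained[:5].tolist(),
        "angles": angles,
        "level_comparisons": comp_frame.to_dict(orient="records"),
        "jackknife": [
            {k: v for k, v in j.to_json_dict().items() if k != "estimates"}
            for j in jackknives
        ],
        "go": {
            "mean_jaccard": {
                lv: float(np.mean(v)) for lv, v in go_pair_values["jaccard_go"].items()
            },
            "mean_rho": {
                lv: float(np.mean(v)) for lv, v in go_pair_values["rho_go"].items()
            },
            "term_distributions": go_summary,
        }
        if sets is not None
        else {},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    log.info("run complete: %s", outdir / "summary.json")
    return summary
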