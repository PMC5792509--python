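"""End-to-end orchestration: simulate/ingest -> filter -> relatedness ->
estimator evaluation -> sibship -> colony metrics -> statistics.

A :class:`PipelineConfig` (loadable from YAML) fully determines a run; the
run writes every intermediate artifact under an output directory together
with a JSON manifest recording the config, the master seed, per-stage
timings, and a content hash of each artifact, so identical config + seed
reproduce identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geno_io, kinship, metrics, simeval, stats, syndata
from .matrix import GenotypeMatrix
from .sibship import ErrorModel, infer_maternal_genotypes, reconstruct

logger = logging.getLogger(__name__)


@dataclass
class SpeciesDesign:
    """Synthetic design for one pseudo-species (field-scale defaults)."""

    name: str
    n_trees: int = 14
    workers_per_tree: int = 6
    mean_queens: float = 1.0  # per-tree queen number (fractional mean ok)
    males_per_queen: int = 2
    n_loci: int = 500
    p_sister_queens: float = 0.3
    skew_concentration: float = 0.35
    p_missing: float = 0.3


@dataclass
class PipelineConfig:
    species: list = field(default_factory=lambda: [
        # four pseudo-species spanning the observed polygyny range
        SpeciesDesign("speciesA", n_trees=16, mean_queens=1.2,
                      males_per_queen=4, n_loci=746),
        SpeciesDesign("speciesB", n_trees=14, mean_queens=3.0,
                      males_per_queen=2, n_loci=669),
        SpeciesDesign("speciesC", n_trees=18, mean_queens=1.0,
                      males_per_queen=2, n_loci=764, p_missing=0.16),
        SpeciesDesign("speciesD", n_trees=13, mean_queens=3.5,
                      males_per_queen=2, n_loci=309),
    ])
    input_files: list = field(default_factory=list)  # alternative to species
    filter: geno_io.FilterSettings = field(
        default_factory=geno_io.FilterSettings)
    estimator_policy: str = "by-simeval"  # or an estimator name
    simeval_pairs: int = 100
    error_model: ErrorModel = field(default_factory=ErrorModel)
    search: str = "anneal"
    min_offspring: int = 4
    maternal_threshold: float = 0.90
    seed: int = 0

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = PipelineConfig()
        if "species" in raw:
            cfg.species = [SpeciesDesign(**s) for s in raw["species"]]
        if "filter" in raw:
            cfg.filter = geno_io.FilterSettings(**raw["filter"])
        if "error_model" in raw:
            cfg.error_model = ErrorModel(**raw["error_model"])
        for key in ("input_files", "estimator_policy", "simeval_pairs",
                    "search", "min_offspring", "maternal_threshold", "seed"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_species(design: SpeciesDesign, rng: np.random.Generator
                      ) -> tuple[GenotypeMatrix, list, pd.DataFrame]:
    """One species: per-tree simulation with a possibly fractional mean
    queen number (each tree draws floor or ceil to match the mean), plus
    independent tree-height covariates."""
    freqs = syndata.draw_allele_frequencies(
        design.n_loci, 0.1, 0.5, seed=int(rng.integers(2**31)))
    base = int(np.floor(design.mean_queens))
    frac = design.mean_queens - base
    mats, truths = [], []
    for t in range(design.n_trees):
        q = base + int(rng.random() < frac)
        d = syndata.ColonyDesign(
            n_trees=1, workers_per_tree=design.workers_per_tree,
            queens_per_tree=max(q, 1),
            males_per_queen=design.males_per_queen,
            skew_concentration=design.skew_concentration,
            p_sister_queens=design.p_sister_queens,
            p_missing=design.p_missing,
            seed=int(rng.integers(2**31)), species_name=design.name)
        G, truth = syndata.simulate_colonies(d, freqs, noisy=True)
        G.tree[:] = f"{design.name}_tree{t}"
        G.ids[:] = [f"{design.name}_t{t}_{w}" for w in G.ids]
        mats.append(G)
        truths.append(truth)
    heights = pd.DataFrame({
        "tree": [f"{design.name}_tree{t}" for t in range(design.n_trees)],
        "species": design.name,
        "height_m": rng.uniform(1.5, 7.0, size=design.n_trees).round(2),
    })
    return GenotypeMatrix.concat(mats), truths, heights


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}

    def artifact(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path),
                                       "sha256": _sha256(path)}

    def stage(name):
        t0 = time.time()

        def done(**info):
            manifest["stages"][name] = {
                "seconds": round(time.time() - t0, 3), **info}
        return done

    # -- stage 1: simulate or ingest ---------------------------------------
    end = stage("input")
    heights_frames = []
    if config.input_files:
        parts_by_species = {}
        for path in config.input_files:
            m = geno_io.read_genotypes(path)
            for sp in dict.fromkeys(m.species):
                if sp in parts_by_species:
                    raise ValueError(f"species {sp!r} appears in two inputs")
                parts_by_species[sp] = m.subset_species(sp)
        heights = pd.DataFrame(columns=["tree", "species", "height_m"])
    else:
        parts = []
        for design in config.species:
            G_sp, _truths, h = _simulate_species(design, rng)
            parts.append(G_sp)
            heights_frames.append(h)
            geno_io.write_tsv(G_sp, out / f"genotypes_{design.name}.tsv")
            artifact(f"genotypes_{design.name}",
                     out / f"genotypes_{design.name}.tsv")
        heights = pd.concat(heights_frames, ignore_index=True)
        G_all = None  # species have different loci; kept separate
        parts_by_species = {m.species[0]: m for m in parts}
    heights.to_csv(out / "tree_heights.tsv", sep="\t", index=False)
    artifact("tree_heights", out / "tree_heights.tsv")
    end(n_species=len(parts_by_species))

    # -- stage 2: filter ----------------------------------------------------
    end = stage("filter")
    filtered = {}
    for sp, G_sp in parts_by_species.items():
        filtered[sp] = geno_io.apply_filters(G_sp, config.filter)
        geno_io.write_tsv(filtered[sp], out / f"filtered_{sp}.tsv")
        artifact(f"filtered_{sp}", out / f"filtered_{sp}.tsv")
    end(loci={sp: g.n_loci for sp, g in filtered.items()})

    # -- stage 3: estimator evaluation -------------------------------------
    end = stage("simeval")
    chosen = {}
    eval_frames = []
    for sp, G_sp in filtered.items():
        freqs = kinship.sample_allele_frequencies(G_sp)
        if config.estimator_policy == "by-simeval":
            evals = simeval.evaluate_estimators(
                freqs, n_pairs=config.simeval_pairs,
                seed=int(rng.integers(2**31)))
            chosen[sp] = simeval.select_estimator(evals)
            rep = simeval.evaluation_report(evals)
            rep.insert(0, "species", sp)
            eval_frames.append(rep)
        else:
            chosen[sp] = config.estimator_policy
    if eval_frames:
        pd.concat(eval_frames, ignore_index=True).to_csv(
            out / "estimator_evaluation.tsv", sep="\t", index=False)
        artifact("estimator_evaluation", out / "estimator_evaluation.tsv")
    end(estimator=chosen)

    # -- stage 4: relatedness ----------------------------------------------
    end = stage("relatedness")
    summaries = {}
    for sp, G_sp in filtered.items():
        freqs = kinship.sample_allele_frequencies(G_sp)
        est = kinship.pairwise_relatedness(G_sp, freqs, chosen[sp])
        est.to_csv(out / f"relatedness_{sp}.tsv", sep="\t", index=False)
        artifact(f"relatedness_{sp}", out / f"relatedness_{sp}.tsv")
        summaries[sp] = kinship.aggregate_within_between(est, G_sp)
    end()

    # -- stage 5: sibship ---------------------------------------------------
    end = stage("sibship")
    configs = {}
    mothers_by_species = {}
    for sp, G_sp in filtered.items():
        freqs = kinship.sample_allele_frequencies(G_sp)
        configs[sp] = {}
        mother_mats = []
        for tree in dict.fromkeys(G_sp.tree):
            workers = G_sp.subset_tree(tree)
            cfg = reconstruct(workers, freqs, config.error_model,
                              search=config.search,
                              seed=int(rng.integers(2**31)))
            configs[sp][tree] = cfg
            mother_mats.append(infer_maternal_genotypes(
                cfg, tree, threshold=config.maternal_threshold, species=sp))
        mothers_by_species[sp] = GenotypeMatrix.concat(mother_mats)
        blob = {
            tree: {
                "families": cfg.families,
                "log_likelihood": cfg.log_likelihood,
                "candidate_assigned": cfg.candidate_assigned,
            } for tree, cfg in configs[sp].items()}
        (out / f"sibship_{sp}.json").write_text(json.dumps(blob, indent=1))
        artifact(f"sibship_{sp}", out / f"sibship_{sp}.json")
    end()

    # -- stage 6: metrics ---------------------------------------------------
    end = stage("metrics")
    per_tree_metrics = {}
    kin_tables = {}
    species_rows = []
    for sp in filtered:
        per_tree_metrics[sp] = [
            metrics.polygyny_polyandry(cfg, tree,
                                       min_offspring=config.min_offspring)
            for tree, cfg in configs[sp].items()]
        mt = metrics.metrics_table(per_tree_metrics[sp])
        mt.insert(0, "species", sp)
        mt.to_csv(out / f"colony_metrics_{sp}.tsv", sep="\t", index=False)
        artifact(f"colony_metrics_{sp}", out / f"colony_metrics_{sp}.tsv")
        s = summaries[sp]
        summary = metrics.species_summary(per_tree_metrics[sp])
        species_rows.append({
            "species": sp,
            "trees": len(per_tree_metrics[sp]),
            "between_tree_r": s.between_mean, "between_tree_se": s.between_se,
            "within_tree_r": s.within_mean, "within_tree_se": s.within_se,
            **{f"{row.metric}_mean": row.mean
               for row in summary.itertuples()},
            **{f"{row.metric}_se": row.se for row in summary.itertuples()},
        })
        freqs = kinship.sample_allele_frequencies(filtered[sp])
        kin_tables[sp] = metrics.queen_kinship(
            mothers_by_species[sp], freqs, config.error_model,
            search=config.search, seed=int(rng.integers(2**31)))
        metrics.kinship_table(kin_tables[sp]).to_csv(
            out / f"queen_kinship_{sp}.tsv", sep="\t", index=False)
        artifact(f"queen_kinship_{sp}", out / f"queen_kinship_{sp}.tsv")
    species_table = pd.DataFrame(species_rows)
    species_table.to_csv(out / "species_summary.tsv", sep="\t", index=False)
    artifact("species_summary", out / "species_summary.tsv")
    end()

    # -- stage 7: statistics ------------------------------------------------
    end = stage("stats")
    reports = []
    heights_map = dict(zip(heights["tree"], heights["height_m"]))

    def stacked(metric_fn):
        vals, labs, trees = [], [], []
        for sp, ms in per_tree_metrics.items():
            for m in ms:
                vals.append(metric_fn(m))
                labs.append(sp)
                trees.append(m.tree)
        return np.array(vals, dtype=float), np.array(labs), trees

    def try_compare(vals, labs, family, metric):
        try:
            reports.append(stats.compare_species(vals, labs, family=family,
                                                 metric=metric))
        except ValueError as exc:
            logger.warning("skipping species comparison for %s: %s",
                           metric, exc)

    within_vals, within_labs = [], []
    for sp, s in summaries.items():
        within_vals.extend(s.per_tree["mean_r"])
        within_labs.extend([sp] * len(s.per_tree))
        reports.append(stats.ttest_vs_zero(
            s.per_tree_pair["mean_r"].to_numpy(),
            metric=f"between-tree relatedness ({sp})"))
    try_compare(within_vals, within_labs, "anova+tukey",
                "within-tree relatedness")

    for name, fn, family in [
        ("polygyny_index", lambda m: m.polygyny_index, "kwt+nemenyi"),
        ("polyandry_index", lambda m: m.polyandry_index, "kwt+nemenyi"),
    ]:
        vals, labs, trees = stacked(fn)
        try_compare(vals, labs, family, name)
        if heights_map:
            h = np.array([heights_map[t] for t in trees])
            reports.extend(stats.tree_size_effects(
                vals, h, labs, method="spearman", metric=name))

    mpq_vals, mpq_labs = [], []
    for sp, ms in per_tree_metrics.items():
        for m in ms:
            mpq_vals.extend(m.males_per_queen)
            mpq_labs.extend([sp] * len(m.males_per_queen))
    if len(set(mpq_labs)) >= 2:
        try_compare(mpq_vals, mpq_labs, "anova+tukey", "males_per_queen")

    for sp, kt in kin_tables.items():
        if kt.contingency().sum() > 0:
            r = stats.fisher_queen_sibship(kt)
            r.grouping = f"queen sibship ({sp})"
            reports.append(r)

    report = stats.report_frame(reports)
    report.to_csv(out / "stat_reports.tsv", sep="\t", index=False)
    artifact("stat_reports", out / "stat_reports.tsv")
    post = [
        {"test": r.test, "grouping": r.grouping,
         "post_hoc": r.post_hoc.to_dict("records")}
        for r in reports if r.post_hoc is not None]
    (out / "post_hoc.json").write_text(json.dumps(post, indent=1))
    artifact("post_hoc", out / "post_hoc.json")
    end(n_tests=len(reports))

    manifest["config_hash"] = hashlib.sha256(
        json.dumps(_config_dict(config), sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d
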