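"""End-to-end orchestration: scan -> null -> enrichment -> conservation -> CAI
-> expression -> fitness, driven by one config and one seed.

Each stage writes its result tables under the output directory and a run
manifest (config, seed, versions, per-stage row counts) sufficient to re-run
any stage.  Two runs with identical config and seed produce byte-identical
bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from . import codon, conservation, enrichment, expression, null_model
from .motif import compile_profile, count_in_windows, call_targets, scan_dataset
from .simulate import FERMENTATIVE, NON_FERMENTATIVE, TRANSLATION_SET, load_bundle_inputs

logger = logging.getLogger(__name__)

ALL_STAGES = ("scan", "windows", "regression", "categories", "conservation",
              "cai", "expression", "fitness")


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; defaults are the study constants
    (1,000 bp region, 50 bp windows, 250 bp target rule, 10,000 null
    sequences, alpha 0.01, 1.5-fold threshold)."""

    input_dir: str = "."
    out_dir: str = "results"
    profile: str = "TGTANATA"
    region_length: int = 1000
    window_size: int = 50
    utr_cutoff: int = 250
    n_null: int = 10_000
    alpha: float = 0.01
    fold: float = 1.5
    correlation: str = "pearson"
    gc_mode: str = "full_region"
    bonferroni_scope: str = "species"
    background: str = "all"
    ortholog_policy: str = "all"
    mito_compartment: str = "mitochondrion"
    function_set: str = TRANSLATION_SET
    conservation_window: int = 50
    fermentative_condition: str = FERMENTATIVE
    nonfermentative_condition: str = NON_FERMENTATIVE
    focal_species: str | None = None
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("region_length", "window_size", "utr_cutoff", "n_null"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}; valid: {ALL_STAGES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _species_seed(master_seed: int, index: int) -> int:
    """Stable per-species null seed below 2**31 derived from the master seed."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0] % (2**31))


def run_all(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute every enabled stage on the input bundle; returns result tables."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profile = compile_profile(config.profile)
    inputs = load_bundle_inputs(config.input_dir)
    species_table: pd.DataFrame = inputs["species_table"]
    datasets = inputs["datasets"]
    orthologs = inputs["orthologs"]
    annotation = inputs["annotation"]
    species_ids = sorted(datasets)
    results: dict[str, pd.DataFrame] = {}
    stage_rows: dict[str, int] = {}

    def _stage_done(name: str, tables: dict[str, pd.DataFrame]) -> None:
        n = sum(len(t) for t in tables.values())
        stage_rows[name] = n
        logger.info("stage %-12s %6.1fs rows=%d", name, time.time() - t_start, n)

    # ----- scan: matches, window counts, targets -------------------------
    matches_by_sp: dict[str, dict] = {}
    targets_by_sp: dict[str, object] = {}
    window_counts_by_sp: dict[str, object] = {}
    if "scan" in config.stages or {"windows", "regression", "categories",
                                   "conservation", "cai", "expression",
                                   "fitness"} & set(config.stages):
        match_rows, window_rows, target_rows = [], [], []
        for sp in species_ids:
            ds = datasets[sp]
            matches = scan_dataset(ds, profile)
            matches_by_sp[sp] = matches
            lengths = {g: len(ds.downstream[g]) for g in matches}
            wc = count_in_windows(matches, lengths, config.window_size, config.region_length)
            window_counts_by_sp[sp] = wc
            targets = call_targets(ds, profile, utr_cutoff=config.utr_cutoff)
            targets_by_sp[sp] = targets
            for gene in sorted(matches):
                for s in matches[gene].starts:
                    match_rows.append({"species_id": sp, "gene": gene, "start": s})
            for w in range(wc.n_windows):
                window_rows.append(
                    {"species_id": sp, "window_start": w * wc.window_size,
                     "window_end": (w + 1) * wc.window_size,
                     "count": int(wc.counts[w]),
                     "eligible": int(wc.eligible_positions[w])}
                )
            target_rows.extend({"species_id": sp, "gene": g} for g in sorted(targets.targets))
        results["matches"] = pd.DataFrame(match_rows, columns=["species_id", "gene", "start"])
        results["window_counts"] = pd.DataFrame(window_rows)
        results["targets"] = pd.DataFrame(target_rows, columns=["species_id", "gene"])
        pio.write_results(results["matches"], out / "matches.tsv")
        pio.write_results(results["window_counts"], out / "window_counts.tsv")
        pio.write_results(results["targets"], out / "targets.tsv")
        _stage_done("scan", {k: results[k] for k in ("matches", "window_counts", "targets")})

    # ----- windows: GC-matched null + per-window Fisher ------------------
    if "windows" in config.stages:
        n_windows = config.region_length // config.window_size
        bonf_n = n_windows * len(species_ids) if config.bonferroni_scope == "global" else None
        frames = []
        for idx, sp in enumerate(species_ids):
            gc_model = null_model.estimate_gc(
                datasets[sp], config.gc_mode, config.window_size, config.region_length
            )
            null = null_model.generate_null(
                gc_model, profile, n=config.n_null, length=config.region_length,
                seed=_species_seed(config.seed, idx), window_size=config.window_size,
            )
            table = null_model.window_enrichment_test(
                window_counts_by_sp[sp], null, alpha=config.alpha, bonferroni_n=bonf_n
            )
            table.insert(0, "species_id", sp)
            gc_val = gc_model.gc if np.ndim(gc_model.gc) == 0 else float(np.mean(gc_model.gc))
            table.insert(1, "gc", float(gc_val))
            frames.append(table)
        results["window_enrichment"] = pd.concat(frames, ignore_index=True)
        pio.write_results(results["window_enrichment"], out / "window_enrichment.tsv")
        _stage_done("windows", {"window_enrichment": results["window_enrichment"]})

    # ----- regression: GC vs motif-gene count ----------------------------
    if "regression" in config.stages:
        fit = null_model.gc_vs_target_regression(
            [datasets[sp] for sp in species_ids], profile, utr_cutoff=config.utr_cutoff
        )
        results["gc_regression"] = pd.DataFrame(
            [{"slope": fit.slope, "intercept": fit.intercept,
              "r_squared": fit.r_squared, "p_value": fit.pvalue, "n_species": fit.n}]
        )
        pio.write_results(results["gc_regression"], out / "gc_regression.tsv")
        _stage_done("regression", {"gc_regression": results["gc_regression"]})

    # ----- categories: localization enrichment + clade contrast ----------
    categories_by_sp: dict[str, dict] = {}
    if {"categories", "cai", "expression", "fitness"} & set(config.stages):
        for sp in species_ids:
            categories_by_sp[sp] = enrichment.map_categories(
                orthologs[sp], annotation, policy=config.ortholog_policy
            )
    if "categories" in config.stages:
        frames = []
        fractions: dict[str, float] = {}
        for sp in species_ids:
            table = enrichment.category_test(
                targets_by_sp[sp], categories_by_sp[sp], set(datasets[sp].genes),
                alpha=config.alpha, background=config.background,
            )
            frames.append(table)
            fractions[sp] = enrichment.category_target_fraction(
                targets_by_sp[sp], categories_by_sp[sp], config.mito_compartment
            )
        results["category_enrichment"] = pd.concat(frames, ignore_index=True)
        pio.write_results(results["category_enrichment"], out / "category_enrichment.tsv")
        frac = pd.DataFrame(
            [{"species_id": sp, "mito_target_fraction": fractions[sp]} for sp in species_ids]
        )
        clade_of = dict(zip(species_table["species_id"], species_table["clade"]))
        frac["clade"] = frac["species_id"].map(clade_of)
        clades = sorted({c for c in clade_of.values()})
        clade_rows = []
        if len(clades) >= 2:
            counts = {c: sum(1 for v in clade_of.values() if v == c) for c in clades}
            testable = [c for c in clades if counts[c] >= 2]
            if len(testable) >= 2:
                t, p = enrichment.clade_fraction_compare(
                    fractions, clade_of, testable[0], testable[1]
                )
                clade_rows.append({"clade_a": testable[0], "clade_b": testable[1],
                                   "t_statistic": t, "p_value": p})
        results["mito_fractions"] = frac
        results["clade_comparison"] = pd.DataFrame(
            clade_rows, columns=["clade_a", "clade_b", "t_statistic", "p_value"]
        )
        pio.write_results(results["mito_fractions"], out / "mito_fractions.tsv")
        pio.write_results(results["clade_comparison"], out / "clade_comparison.tsv")
        _stage_done("categories", {k: results[k] for k in
                                   ("category_enrichment", "mito_fractions", "clade_comparison")})

    # ----- conservation matrix + sliding function fraction ---------------
    if "conservation" in config.stages:
        mito_genes = {g for g, c in annotation.localization.items()
                      if c == config.mito_compartment}
        per_species = {sp: (targets_by_sp[sp], orthologs[sp]) for sp in species_ids}
        matrix = conservation.build_matrix(mito_genes, per_species)
        letters = matrix.to_letters()
        letters.insert(0, "row_score", matrix.row_score.round(6))
        letters.index.name = "gene"
        letters = letters.reset_index()
        results["conservation_matrix"] = letters
        pio.write_results(letters, out / "conservation_matrix.tsv")
        function_set = annotation.function_sets.get(config.function_set, set())
        window = min(config.conservation_window, len(matrix.genes))
        fractions_df = conservation.sliding_function_fraction(matrix, function_set, window=window)
        results["conservation_fractions"] = fractions_df
        pio.write_results(fractions_df, out / "conservation_fractions.tsv")
        _stage_done("conservation", {"conservation_matrix": letters,
                                     "conservation_fractions": fractions_df})

    # ----- CAI: per-gene values and the pre/post-WGD contrast ------------
    if "cai" in config.stages:
        ribosomal = set(inputs["ribosomal"])
        wgd_of = dict(zip(species_table["species_id"], species_table["wgd"].astype(str)))
        cai_rows = []
        species_means: list[dict] = []
        for sp in species_ids:
            ds = datasets[sp]
            ref_of = orthologs[sp].by_species_gene()
            ref_cds = [ds.cds[g] for g in sorted(ds.cds)
                       if ref_of.get(g, set()) & ribosomal]
            if not ref_cds:
                raise ValueError(f"{sp}: no ribosomal reference orthologs with CDS")
            weights = codon.reference_weights(ref_cds)
            values = codon.cai_table(ds.cds, weights)
            genes_sorted = sorted(values)
            z = codon.standardize([values[g] for g in genes_sorted])
            z_of = dict(zip(genes_sorted, z))
            mito_cats = categories_by_sp[sp]
            tset = targets_by_sp[sp].targets
            group_of = {}
            for g in genes_sorted:
                if config.mito_compartment in mito_cats.get(g, set()):
                    group_of[g] = "mito_with_P3E" if g in tset else "mito_without_P3E"
                else:
                    group_of[g] = "other"
            for g in genes_sorted:
                cai_rows.append({"species_id": sp, "gene": g, "cai": values[g],
                                 "cai_z": z_of[g], "group": group_of[g]})
            for grp in ("mito_with_P3E", "mito_without_P3E"):
                members = [g for g in genes_sorted if group_of[g] == grp]
                if members:
                    species_means.append(
                        {"species_id": sp, "wgd": wgd_of.get(sp, ""), "group": grp,
                         "n_genes": len(members),
                         "mean_cai": float(np.mean([values[g] for g in members])),
                         "mean_cai_z": float(np.mean([z_of[g] for g in members]))}
                    )
        results["cai_values"] = pd.DataFrame(cai_rows)
        means_df = pd.DataFrame(species_means)
        results["cai_species_means"] = means_df
        pio.write_results(results["cai_values"], out / "cai_values.tsv")
        pio.write_results(means_df, out / "cai_species_means.tsv")
        compare_rows = []
        for grp in ("mito_with_P3E", "mito_without_P3E"):
            sub = means_df[means_df["group"] == grp]
            pre = sub.loc[sub["wgd"] == "pre", "mean_cai_z"].to_list()
            post = sub.loc[sub["wgd"] == "post", "mean_cai_z"].to_list()
            if len(pre) >= 2 and len(post) >= 2:
                t, p = codon.group_compare(post, pre)
                compare_rows.append({"group": grp, "n_post": len(post), "n_pre": len(pre),
                                     "t_statistic": t, "p_value": p})
        results["cai_wgd_comparison"] = pd.DataFrame(
            compare_rows, columns=["group", "n_post", "n_pre", "t_statistic", "p_value"]
        )
        pio.write_results(results["cai_wgd_comparison"], out / "cai_wgd_comparison.tsv")
        _stage_done("cai", {k: results[k] for k in
                            ("cai_values", "cai_species_means", "cai_wgd_comparison")})

    # ----- expression: regulation classes + co-expression ----------------
    focal = config.focal_species
    if focal is None:
        manifest_in = inputs.get("manifest", {})
        focal = manifest_in.get("focal_species", species_ids[0])
    if "expression" in config.stages:
        if "expression" not in inputs:
            raise ValueError("expression stage enabled but expression.tsv is missing")
        matrix = inputs["expression"]
        with_ref, without_ref = _reference_mito_groups(
            focal, orthologs, targets_by_sp, categories_by_sp, annotation,
            config.mito_compartment, set(matrix.index),
        )
        counts_with = expression.classify_regulation(
            matrix, config.fermentative_condition, config.fold, with_ref, group="with_P3E"
        )
        counts_without = expression.classify_regulation(
            matrix, config.fermentative_condition, config.fold, without_ref, group="without_P3E"
        )
        assoc = expression.regulation_association(counts_with, counts_without)
        results["regulation"] = pd.DataFrame(
            [{"group": c.group, "n_down": c.n_down, "n_up": c.n_up,
              "n_unchanged": c.n_unchanged, "down_up_ratio": c.down_up_ratio}
             for c in (counts_with, counts_without)]
        )
        results["regulation_association"] = pd.DataFrame(
            [{"odds_ratio": assoc.odds_ratio, "p_value": assoc.pvalue,
              "ratio_with": assoc.ratio_with, "ratio_without": assoc.ratio_without}]
        )
        dists = expression.pairwise_correlation_distributions(
            matrix, with_ref, without_ref, method=config.correlation
        )
        dist_rows = [{"pair_type": name, "r": float(r)}
                     for name in ("within_a", "within_b", "between")
                     for r in dists[name]]
        results["correlations"] = pd.DataFrame(dist_rows, columns=["pair_type", "r"])
        t_ab, p_ab = expression.compare_distributions(dists["within_a"], dists["within_b"])
        results["correlation_comparison"] = pd.DataFrame(
            [{"comparison": "within_with_vs_within_without", "t_statistic": t_ab,
              "p_value": p_ab,
              "mean_within_with": float(np.mean(dists["within_a"])),
              "mean_within_without": float(np.mean(dists["within_b"])),
              "mean_between": float(np.mean(dists["between"]))}]
        )
        for key, fname in (("regulation", "regulation.tsv"),
                           ("regulation_association", "regulation_association.tsv"),
                           ("correlations", "correlations.tsv"),
                           ("correlation_comparison", "correlation_comparison.tsv")):
            pio.write_results(results[key], out / fname)
        _stage_done("expression", {k: results[k] for k in
                                   ("regulation", "regulation_association",
                                    "correlations", "correlation_comparison")})

    # ----- fitness: deletion growth contrast per condition ---------------
    if "fitness" in config.stages:
        if "fitness" not in inputs:
            raise ValueError("fitness stage enabled but fitness.tsv is missing")
        fit_df = inputs["fitness"]
        genes_in = set(fit_df["gene"].astype(str))
        with_ref, without_ref = _reference_mito_groups(
            focal, orthologs, targets_by_sp, categories_by_sp, annotation,
            config.mito_compartment, genes_in,
        )
        rows = []
        for condition in sorted(fit_df["condition"].unique()):
            sub = fit_df[fit_df["condition"] == condition].set_index("gene")["relative_growth"]
            a = [float(sub[g]) for g in with_ref if g in sub.index]
            b = [float(sub[g]) for g in without_ref if g in sub.index]
            t, p = codon.group_compare(a, b)
            rows.append({"condition": condition, "n_with": len(a), "n_without": len(b),
                         "mean_with": float(np.mean(a)), "mean_without": float(np.mean(b)),
                         "t_statistic": t, "p_value": p})
        results["fitness_comparison"] = pd.DataFrame(rows)
        pio.write_results(results["fitness_comparison"], out / "fitness_comparison.tsv")
        _stage_done("fitness", {"fitness_comparison": results["fitness_comparison"]})

    _write_manifest(config, out, stage_rows)
    return results


def _reference_mito_groups(focal, orthologs, targets_by_sp, categories_by_sp,
                           annotation, mito_compartment, available: set[str]):
    """Mitochondrial reference genes split by the focal species' target calls."""
    if focal not in orthologs:
        raise ValueError(f"focal species {focal!r} not in bundle")
    ref_of = orthologs[focal].by_species_gene()
    tset = targets_by_sp[focal].targets
    mito_ref = {g for g, c in annotation.localization.items() if c == mito_compartment}
    with_ref, without_ref = set(), set()
    for sp_gene, refs in ref_of.items():
        for r in refs & mito_ref & available:
            (with_ref if sp_gene in tset else without_ref).add(r)
    without_ref -= with_ref  # a reference gene with any target ortholog counts as with
    return sorted(with_ref), sorted(without_ref)


def _write_manifest(config: PipelineConfig, out: Path, stage_rows: dict[str, int]) -> None:
    config_dict = dataclasses.asdict(config)
    config_dict["stages"] = list(config.stages)
    config_json = json.dumps(config_dict, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "stage_rows": stage_rows,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
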