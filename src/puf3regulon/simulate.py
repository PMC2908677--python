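"""Seedable multi-species synthetic data with the structure the pipeline assumes.

The generator emulates the inputs of a comparative regulon study without any
downloads: per-species 3' downstream regions with controlled GC content and
motif instances planted at category-specific rates, CDS with tunable codon
bias relative to a ribosomal-protein reference, 1:1 ortholog maps to a
simulated reference gene list, localization and function-set annotations,
block-correlated expression with a fermentative down-regulation effect for
motif-bearing genes, and deletion-fitness values with a condition-specific
group effect.

Defaults define the demo study: two clades of five species each, 1,000 genes
per species of which 300 are mitochondrial, mitochondrial motif rates 0.5
(saccharomycotina-like clade) vs 0.1 (outgroup), background rate 0.05.
Within the mitochondrial set, a "core" subset linked to mitochondrial
translation carries the motif at an elevated rate, producing the
high-to-low conservation gradient the conservation stage ranks.

Motif planting overwrites bases in place (an admitted 8-mer at a uniform
admissible start within the placement window), preserving sequence length
and window geometry.  All randomness flows from one master seed through
per-stage/per-species spawned streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from . import io as pio
from .codon import SYNONYMOUS_FAMILIES
from .io import AnnotationTable, OrthologMap, SpeciesDataset
from .motif import DEFAULT_PROFILE, MotifProfile, compile_profile

_BASES = np.array(list("ACGT"))

COMPARTMENTS = ("mitochondrion", "cytoplasm", "nucleus", "er", "membrane")
TRANSLATION_SET = "mitochondrial_translation"
FERMENTATIVE = "YPD"
NON_FERMENTATIVE = "YPE"


@dataclass
class CladeSpec:
    """One clade: species count, per-species GC, and mitochondrial motif rate.

    ``wgd`` tags species for the codon-bias contrast: ``"pre"``/``"post"``
    apply to every species, ``"split"`` alternates pre (even species index)
    and post (odd), ``None`` leaves species untagged.
    """

    label: str
    n_species: int
    gc: tuple[float, ...] | float = 0.38
    motif_rate_mito: float = 0.5
    wgd: str | None = None

    def gc_of(self, i: int) -> float:
        if isinstance(self.gc, (int, float)):
            return float(self.gc)
        return float(self.gc[i])

    def wgd_of(self, i: int) -> str:
        if self.wgd is None:
            return ""
        if self.wgd == "split":
            return "pre" if i % 2 == 0 else "post"
        return self.wgd


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the demo conditions."""

    clades: list[CladeSpec] = field(default_factory=lambda: [
        CladeSpec("saccharomycotina", 5, gc=(0.35, 0.37, 0.38, 0.40, 0.42),
                  motif_rate_mito=0.5, wgd="split"),
        CladeSpec("outgroup", 5, gc=(0.45, 0.48, 0.50, 0.53, 0.56),
                  motif_rate_mito=0.1, wgd=None),
    ])
    n_genes: int = 1000
    n_mito: int = 300
    downstream_length: int = 1000
    placement_window: int = 250
    profile: str = DEFAULT_PROFILE
    motif_rate_background: float = 0.05
    # conservation structure within the mitochondrial set
    core_fraction: float = 0.4
    core_enrichment: float = 1.8
    translation_in_core: float = 0.8
    translation_in_other: float = 0.04
    ortholog_presence: float = 0.9
    # coding sequences and codon bias
    cds_codons: int = 200
    codon_bias_mean: float = 0.5
    codon_bias_sd: float = 0.15
    reference_bias: float = 0.9
    n_reference_genes: int = 30
    cai_z_shift: float = -0.5
    # expression compendium
    n_conditions: int = 1011
    expression_rho: float = 0.5
    expression_shift: float = 1.0
    expression_sd: float = 0.5
    # deletion fitness
    fitness_mean: float = 1.0
    fitness_sd: float = 0.1
    fitness_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mito > self.n_genes:
            raise ValueError(f"n_mito ({self.n_mito}) > n_genes ({self.n_genes})")
        for r in (self.motif_rate_background, self.core_fraction, self.ortholog_presence,
                  self.translation_in_core, self.translation_in_other, self.expression_rho):
            if not 0 <= r <= 1:
                raise ValueError(f"rate {r} outside [0, 1]")
        for clade in self.clades:
            for i in range(clade.n_species):
                if not 0 <= clade.gc_of(i) <= 1:
                    raise ValueError(f"gc {clade.gc_of(i)} outside [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def default_demo_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The demo study configuration with a chosen master seed."""
    return SimulationConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# reference species
# ---------------------------------------------------------------------------


@dataclass
class ReferenceDesignations:
    """Simulated reference-species gene list with category designations."""

    genes: list[str]
    mito: set[str]
    core: set[str]  # mitochondrial genes with elevated motif conservation
    translation: set[str]
    ribosomal: list[str]  # cytoplasmic ribosomal reference genes (CAI reference)
    annotation: AnnotationTable


def simulate_reference(config: SimulationConfig, rng: np.random.Generator) -> ReferenceDesignations:
    genes = [f"R{i:04d}" for i in range(1, config.n_genes + 1)]
    mito = set(genes[: config.n_mito])
    n_core = round(config.core_fraction * config.n_mito)
    core = set(genes[:n_core])
    translation = set()
    for g in genes[: config.n_mito]:
        p = config.translation_in_core if g in core else config.translation_in_other
        if rng.random() < p:
            translation.add(g)
    if not translation:
        translation = set(genes[:1])  # function sets must be non-empty
    ribosomal = [f"RIB{j:03d}" for j in range(1, config.n_reference_genes + 1)]
    localization = {}
    others = [c for c in COMPARTMENTS if c != "mitochondrion"]
    for i, g in enumerate(genes):
        localization[g] = "mitochondrion" if g in mito else others[i % len(others)]
    for g in ribosomal:
        localization[g] = "cytoplasm"
    annotation = AnnotationTable(
        localization=localization,
        function_sets={TRANSLATION_SET: translation},
        compartments=COMPARTMENTS,
    )
    return ReferenceDesignations(
        genes=genes, mito=mito, core=core, translation=translation,
        ribosomal=ribosomal, annotation=annotation,
    )


# ---------------------------------------------------------------------------
# per-species sequences
# ---------------------------------------------------------------------------


def _random_sequences(gc: float, n: int, length: int, rng: np.random.Generator) -> list[str]:
    u = rng.random((n, length))
    codes = np.zeros((n, length), dtype=np.int64)
    codes[u >= (1 - gc) / 2] = 1  # C
    codes[u >= 0.5] = 2           # G  (cumulative A + C = 1/2 by symmetry)
    codes[u >= 0.5 + gc / 2] = 3  # T
    chars = _BASES[codes]
    return ["".join(row) for row in chars]


def _plant_motif(seq: str, profile: MotifProfile, placement_window: int,
                 rng: np.random.Generator) -> str:
    words = profile.admitted_words()
    word = words[rng.integers(len(words))]
    max_start = min(placement_window, len(seq)) - len(word)
    if max_start < 0:
        raise ValueError("placement window shorter than the motif")
    start = int(rng.integers(max_start + 1))
    return seq[:start] + word + seq[start + len(word):]


def _motif_rates(config: SimulationConfig, clade: CladeSpec) -> tuple[float, float]:
    """Per-gene motif rates for core vs other mitochondrial genes.

    The core subset carries the motif at ``core_enrichment`` times the clade
    rate (capped at 1); the remainder absorbs the difference so the
    mitochondrial mean equals the clade's configured rate.
    """
    f = config.core_fraction
    r = clade.motif_rate_mito
    r_core = min(1.0, r * config.core_enrichment)
    r_other = (r - f * r_core) / (1 - f) if f < 1 else r
    return r_core, max(0.0, r_other)


def _deterministic_cai(bias: np.ndarray, reference_bias: float) -> np.ndarray:
    """Large-gene limit of CAI as a function of the codon-bias parameter.

    With the mixture sampler below, a codon of a size-k family is the
    preferred codon with probability b + (1-b)/k, else one of the k-1
    non-preferred codons, whose reference weight is
    ((1-r)/k) / (r + (1-r)/k) for reference bias r.  CAI converges to
    exp(E[log w]) as gene length grows.
    """
    bias = np.asarray(bias, dtype=float)
    log_sum = np.zeros_like(bias)
    fams = sorted(SYNONYMOUS_FAMILIES)
    r = reference_bias
    for aa in fams:
        k = len(SYNONYMOUS_FAMILIES[aa])
        w_np = ((1 - r) / k) / (r + (1 - r) / k)
        log_sum += (1 - bias) * (k - 1) / k * np.log(w_np)
    return np.exp(log_sum / len(fams))


def _calibrated_bias_shift(config: "SimulationConfig") -> float:
    """Bias-parameter shift realising ``cai_z_shift`` standard deviations of CAI.

    CAI is a convex function of the bias parameter, so a shift expressed in
    bias s.d. does not translate one-to-one into CAI z-units; this solves for
    the downward bias shift whose mean CAI change equals ``cai_z_shift``
    times the genome-wide CAI s.d. (both evaluated on the deterministic
    bias -> CAI map over the configured bias distribution).
    """
    if config.cai_z_shift == 0:
        return 0.0
    if config.cai_z_shift > 0:
        raise ValueError("cai_z_shift must be <= 0 (codon-bias relaxation)")
    qs = (np.arange(401) + 0.5) / 401
    b = np.clip(sps.norm.ppf(qs, config.codon_bias_mean, config.codon_bias_sd), 0.02, 0.98)
    base = _deterministic_cai(b, config.reference_bias)
    target = config.cai_z_shift * base.std(ddof=1)

    def gap(d: float) -> float:
        shifted = _deterministic_cai(np.clip(b - d, 0.02, 0.98), config.reference_bias)
        return float(shifted.mean() - base.mean() - target)

    max_shift = config.codon_bias_mean + 3 * config.codon_bias_sd
    if gap(max_shift) > 0:  # requested depression beyond what clipping allows
        return max_shift
    return float(optimize.brentq(gap, 0.0, max_shift, xtol=1e-6))


def _sample_cds(bias: np.ndarray, n_codons: int, rng: np.random.Generator) -> list[str]:
    """Vectorised CDS sampling: per codon slot a uniform amino-acid family,
    then the family's preferred codon with probability ``bias`` else a
    uniform family member.  ATG is prepended and TAA appended."""
    families = sorted(SYNONYMOUS_FAMILIES)
    fam_codons = [SYNONYMOUS_FAMILIES[aa] for aa in families]
    max_size = max(len(c) for c in fam_codons)
    codon_lut = np.empty((len(families), max_size), dtype="<U3")
    sizes = np.zeros(len(families), dtype=np.int64)
    for i, codons in enumerate(fam_codons):
        sizes[i] = len(codons)
        for j, c in enumerate(codons):
            codon_lut[i, j] = c
        codon_lut[i, len(codons):] = codons[0]
    preferred = np.array([codons[0] for codons in fam_codons])

    g = len(bias)
    aa = rng.integers(0, len(families), size=(g, n_codons))
    take_pref = rng.random((g, n_codons)) < bias[:, None]
    within = (rng.random((g, n_codons)) * sizes[aa]).astype(np.int64)
    chosen = np.where(take_pref, preferred[aa], codon_lut[aa, within])
    return ["ATG" + "".join(row) + "TAA" for row in chosen]


def simulate_species(
    config: SimulationConfig,
    clade: CladeSpec,
    species_index: int,
    reference: ReferenceDesignations,
    seed_seq: np.random.SeedSequence,
) -> tuple[SpeciesDataset, OrthologMap, set[str]]:
    """One species' sequences, its ortholog map, and its motif designations.

    Returns the dataset, the 1:1 ortholog map to the reference gene list
    (with genes missing at rate ``1 - ortholog_presence``), and the set of
    species genes that received a planted motif.
    """
    rng = np.random.default_rng(seed_seq)
    sp = f"{clade.label}_s{species_index + 1:02d}"
    gc = clade.gc_of(species_index)
    wgd = clade.wgd_of(species_index)
    profile = compile_profile(config.profile)
    r_core, r_other = _motif_rates(config, clade)

    present = [g for g in reference.genes if rng.random() < config.ortholog_presence]
    ref_ids = present + reference.ribosomal  # ribosomal reference genes always present
    sp_ids = [f"{sp}_{r.lower()}" for r in ref_ids]
    pairs = set(zip(sp_ids, ref_ids))

    downstream_seqs = _random_sequences(gc, len(ref_ids), config.downstream_length, rng)
    designated: set[str] = set()
    downstream: dict[str, str] = {}
    for sp_gene, ref_gene, seq in zip(sp_ids, ref_ids, downstream_seqs):
        if ref_gene in reference.ribosomal:
            rate = 0.0
        elif ref_gene in reference.core:
            rate = r_core
        elif ref_gene in reference.mito:
            rate = r_other
        else:
            rate = config.motif_rate_background
        if rate > 0 and rng.random() < rate:
            seq = _plant_motif(seq, profile, config.placement_window, rng)
            designated.add(sp_gene)
        downstream[sp_gene] = seq

    bias = np.clip(
        rng.normal(config.codon_bias_mean, config.codon_bias_sd, size=len(ref_ids)),
        0.02, 0.98,
    )
    bias_shift = _calibrated_bias_shift(config)
    for i, (sp_gene, ref_gene) in enumerate(zip(sp_ids, ref_ids)):
        if ref_gene in reference.ribosomal:
            bias[i] = config.reference_bias
        elif wgd == "post" and ref_gene in reference.mito and sp_gene in designated:
            # codon-bias relaxation planted only in motif-bearing mitochondrial
            # genes of post-WGD species, calibrated to cai_z_shift CAI s.d.
            bias[i] = np.clip(bias[i] - bias_shift, 0.02, 0.98)
    cds_list = _sample_cds(bias, config.cds_codons, rng)
    cds = dict(zip(sp_ids, cds_list))

    label = f"{clade.label}_{wgd}_wgd" if wgd else clade.label
    dataset = SpeciesDataset(species_id=sp, downstream=downstream, cds=cds, label=label)
    orthologs = OrthologMap(species_id=sp, reference_id="reference", pairs=pairs)
    return dataset, orthologs, designated


# ---------------------------------------------------------------------------
# expression and fitness
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig,
    block_genes: list[str],
    other_genes: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Block-correlated log2 expression compendium for two gene groups.

    ``block_genes`` share a within-block Pearson correlation
    ``expression_rho`` (one latent factor per condition) across the
    compendium conditions, and are shifted by a fixed ``-expression_shift``
    in the fermentative condition, whose noise is kept independent so the
    planted down-regulation is a deterministic condition mean rather than a
    random factor draw.  ``other_genes`` are independent noise.  Marginal
    s.d. is ``expression_sd`` everywhere.
    """
    if config.n_conditions < 3:
        raise ValueError("need at least 3 conditions")
    rho, sd = config.expression_rho, config.expression_sd
    if not 0 <= rho < 1:
        raise ValueError("expression_rho must lie in [0, 1)")
    conditions = [FERMENTATIVE] + [f"cond{i:04d}" for i in range(1, config.n_conditions)]
    genes = list(block_genes) + list(other_genes)
    n_b = len(block_genes)
    common = rng.standard_normal(config.n_conditions)
    noise = rng.standard_normal((len(genes), config.n_conditions))
    values = noise * sd
    values[:n_b, 1:] = sd * (np.sqrt(rho) * common[1:] + np.sqrt(1 - rho) * noise[:n_b, 1:])
    values[:n_b, 0] = sd * noise[:n_b, 0] - config.expression_shift
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=conditions)


def simulate_fitness(
    config: SimulationConfig,
    block_genes: list[str],
    other_genes: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Deletion-mutant relative growth in fermentative vs non-fermentative media.

    ``block_genes`` lose ``fitness_effect`` standard deviations of growth in
    the non-fermentative condition only (their deletions matter when
    respiration does); both groups are equivalent in the fermentative medium.
    """
    rows = []
    for condition in (FERMENTATIVE, NON_FERMENTATIVE):
        for group, genes in (("with_motif", block_genes), ("without_motif", other_genes)):
            mean = config.fitness_mean
            if condition == NON_FERMENTATIVE and group == "with_motif":
                mean -= config.fitness_effect * config.fitness_sd
            values = rng.normal(mean, config.fitness_sd, size=len(genes))
            rows.extend(
                {"gene": g, "condition": condition, "relative_growth": float(v)}
                for g, v in zip(genes, values)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    """Everything the pipeline consumes, held in memory."""

    config: SimulationConfig
    reference: ReferenceDesignations
    datasets: dict[str, SpeciesDataset]
    orthologs: dict[str, OrthologMap]
    designated: dict[str, set[str]]  # species -> motif-planted species genes
    species_table: pd.DataFrame  # species_id, clade, wgd, gc
    expression: pd.DataFrame
    fitness: pd.DataFrame
    focal_species: str


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Generate the full multi-species bundle from one master seed."""
    master = np.random.SeedSequence(config.seed)
    ref_seed, expr_seed, fit_seed, species_root = master.spawn(4)
    reference = simulate_reference(config, np.random.default_rng(ref_seed))

    datasets: dict[str, SpeciesDataset] = {}
    orthologs: dict[str, OrthologMap] = {}
    designated: dict[str, set[str]] = {}
    sp_rows = []
    species_seeds = species_root.spawn(sum(c.n_species for c in config.clades))
    k = 0
    for clade in config.clades:
        for i in range(clade.n_species):
            ds, om, des = simulate_species(config, clade, i, reference, species_seeds[k])
            k += 1
            datasets[ds.species_id] = ds
            orthologs[ds.species_id] = om
            designated[ds.species_id] = des
            sp_rows.append(
                {"species_id": ds.species_id, "clade": clade.label,
                 "wgd": clade.wgd_of(i), "gc": clade.gc_of(i)}
            )
    species_table = pd.DataFrame(sp_rows)

    # expression/fitness emulate reference-species measurements over the
    # mitochondrial genes; the block is the focal species' designated set.
    focal = species_table["species_id"].iloc[0]
    ref_of = {s: r for s, r in orthologs[focal].pairs}
    block = sorted({ref_of[g] for g in designated[focal] if ref_of[g] in reference.mito})
    present_mito = sorted({r for r in ref_of.values() if r in reference.mito})
    other = [g for g in present_mito if g not in set(block)]
    expression = simulate_expression(config, block, other, np.random.default_rng(expr_seed))
    fitness = simulate_fitness(config, block, other, np.random.default_rng(fit_seed))
    return StudyBundle(
        config=config, reference=reference, datasets=datasets, orthologs=orthologs,
        designated=designated, species_table=species_table,
        expression=expression, fitness=fitness, focal_species=focal,
    )


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> None:
    """Emit the bundle as plain-text files plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, ds in bundle.datasets.items():
        pio.write_fasta(ds.downstream, outdir / f"downstream_{sp}.fasta")
        pio.write_fasta(ds.cds, outdir / f"cds_{sp}.fasta")
        pio.write_ortholog_map(bundle.orthologs[sp], outdir / f"orthologs_{sp}.tsv")
    pio.write_annotations(
        bundle.reference.annotation,
        outdir / "localization.tsv",
        outdir / "function_sets.tsv",
    )
    pd.DataFrame({"gene": bundle.reference.ribosomal}).to_csv(
        outdir / "ribosomal_reference.tsv", sep="\t", index=False
    )
    bundle.species_table.to_csv(outdir / "species.tsv", sep="\t", index=False)
    pio.write_expression_matrix(bundle.expression, outdir / "expression.tsv")
    bundle.fitness.to_csv(outdir / "fitness.tsv", sep="\t", index=False)
    config_json = json.dumps(bundle.config.to_dict(), sort_keys=True)
    manifest = {
        "seed": bundle.config.seed,
        "focal_species": bundle.focal_species,
        "config": bundle.config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "species": list(bundle.species_table["species_id"]),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_bundle_inputs(indir: str | Path) -> dict:
    """Read a written bundle back into pipeline inputs (no designations)."""
    indir = Path(indir)
    species_table = pio.read_table(indir / "species.tsv", ("species_id", "clade", "wgd", "gc"))
    species_table["wgd"] = species_table["wgd"].fillna("").astype(str)
    datasets: dict[str, SpeciesDataset] = {}
    orthologs: dict[str, OrthologMap] = {}
    for row in species_table.itertuples():
        sp = row.species_id
        datasets[sp] = SpeciesDataset(
            species_id=sp,
            downstream=pio.read_fasta(indir / f"downstream_{sp}.fasta"),
            cds=pio.read_fasta(indir / f"cds_{sp}.fasta"),
            label=str(row.clade),
        )
        orthologs[sp] = pio.read_ortholog_map(indir / f"orthologs_{sp}.tsv", sp)
    annotation = pio.read_annotations(indir / "localization.tsv", indir / "function_sets.tsv")
    ribosomal = list(pio.read_table(indir / "ribosomal_reference.tsv", ("gene",))["gene"].astype(str))
    out = {
        "species_table": species_table,
        "datasets": datasets,
        "orthologs": orthologs,
        "annotation": annotation,
        "ribosomal": ribosomal,
    }
    expr_path = indir / "expression.tsv"
    if expr_path.exists():
        out["expression"] = pio.read_expression_matrix(expr_path)
    fit_path = indir / "fitness.tsv"
    if fit_path.exists():
        out["fitness"] = pio.read_fitness(fit_path)
    manifest_path = indir / "manifest.json"
    if manifest_path.exists():
        out["manifest"] = json.loads(manifest_path.read_text())
    return out
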