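# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `puf3regulon`. It documents what the code computes
and why the open design choices were settled the way they were; every
empirical statement here is one the test suite or `scripts/acceptance.py`
computes itself.

## Motif model and scanning

A motif profile is an ordered list of eight per-position nucleotide sets.
The default, `TGTANATA`, fixes seven sites and frees the fifth; because the
canonical element is published as a logo rather than a machine-readable
profile, the profile is a configurable input with this documented default,
and all statistical properties of the pipeline are profile-agnostic.

Scanning conventions:

- **Sense strand only.** Downstream sequences are mRNA-oriented and the
  element is read on the mRNA; the reverse complement is never scanned.
- **Overlapping matches are all reported** (possible only with non-default
  profiles), and multiple matches in one window count as independent events.
- **`N` in a sequence matches nothing**, so padded or masked bases can never
  create a match.
- **Window assignment is by 0-based start offset**: window
  `floor(start / 50)`. Whether an 8-mer straddling a window boundary should
  instead count toward the next window is genuinely ambiguous; assignment by
  start is the simplest rule and is applied identically to observed and null
  sequences, so enrichment statistics are unaffected by the choice.
- **Target rule**: a gene is a called target when a complete match ends at
  or before base 250 (start ≤ 242, 0-based). A binding element half outside
  the UTR is not a site; the boundary is tested explicitly at 242/243.

The scanner is vectorised (a boolean per-position lookup over a packed
code matrix), which is what makes the simulation-heavy validation feasible;
its exactness is guarded by an independent character-class regex oracle run
over thousands of random sequences at three GC levels.

## GC-matched null model

Chance occurrence of the AT-rich element depends strongly on base
composition, so observed window counts are compared against random
sequences generated at the species' own GC content. Bases are i.i.d. with
the symmetric decomposition P(G) = P(C) = gc/2, P(A) = P(T) = (1 − gc)/2 —
the simplest model consistent with matching a single GC constraint, and
fully reproducible given the seed. Three background dialects are available:
`full_region` (default; GC pooled over the whole 1,000 bp), `utr250` (first
250 bp), and `per_window` (each 50-bp block of the random sequences drawn at
that window's own pooled GC). N bases are excluded from both numerator and
denominator of every GC estimate.

Under this model the per-position match probability has the closed form
Π_i P(allowed_i | gc); for the default profile this is
((1 − gc)/2)⁶ · (gc/2) — six fixed A/T sites, one fixed G site, one free
site — which is zero at gc = 0 and strictly decreasing for gc > 1/7, hence
decreasing over the whole biologically relevant range. The simulated null is
checked against this closed form within three binomial standard deviations.

### The 2×2 unit of the window test

The Fisher table per window compares motif start positions against eligible
start positions (positions whose full 8-mer fits inside the gene and the
region), pooled over genes or random sequences:

    [[obs_count,  obs_eligible  − obs_count ],
     [null_count, null_eligible − null_count]]

Position-level counting is the only construction consistent with treating
multiple occurrences per window as independent events. Genes shorter than
1,000 bp contribute eligible positions only where they exist, so later
windows are not biased downward; random sequences are always full length.

The test is **one-sided (greater)** because only enrichment is interpreted;
depletion of the element in distal windows is not a claim the method makes.
The one-sided Fisher p equals the upper hypergeometric tail and is computed
through `scipy.stats.hypergeom.sf`; the test suite keeps an independent
direct-summation oracle. Bonferroni correction is applied over the 20
windows of one species by default; a `global` scope correcting over all
species' windows is available (`bonferroni_scope`), since either reading of
"multiple comparisons" is defensible. Default α = 0.01 throughout.

Adjacent-window counts from the same sequence set are not independent (an
8-mer's positions span at most two windows), so the per-window p-values are
marginally exact but jointly conservative under Bonferroni; the type-I error
check in the acceptance suite measures the realised family-wise behaviour
directly.

## Orthology transfer and category enrichment

Species genes inherit the compartment of their reference-species orthologs.
A gene with several annotated orthologs keeps **all** their compartments
(multi-membership) by default — any tie-break would be arbitrary — with a
deterministic `best` (lexicographically first reference gene) policy behind
a flag. Genes without an annotated ortholog join no category but stay in the
genome background; the background is all genes with a scanned downstream
region (`background="all"`), with an `annotated`-only restriction behind a
flag.

Per category the upper-tail hypergeometric p is P(X ≥ k) drawing the
category size from the genome with the genome-wide target count as
successes; Bonferroni over the categories tested. The cross-clade
comparison is a two-sample two-tailed t-test on per-species fractions of
mitochondrial genes that are targets — the published analysis reports a
single p-value for this contrast without naming the test, so the t-test on
per-species fractions is documented here as this package's interpretation.

## Conservation matrix

One row per reference gene, one column per species; a cell is `target` if
any ortholog of the gene in that species is a called target (paralog
"any"-semantics), `present_nontarget` if orthologs exist, `absent`
otherwise. The row score is the fraction of **non-absent** cells that are
targets — conservation among orthologs, not among species — and rows absent
everywhere are dropped with a warning. Ties in the ranking are broken by
gene id so rendered output is byte-reproducible. The function-set profile
uses an overlapping window (default 50 genes, step 1, step configurable);
overlapping windows are strongly autocorrelated, so null checks compare the
disjoint first and last windows rather than rank-correlating the profile.

## Codon adaptation index

Relative adaptiveness w(c) = count(c) / max count within the synonymous
family, counts pooled over all copies of the ribosomal-protein reference
orthologs. Codons unobserved in the reference receive a count of 0.5 before
normalisation (the standard convention), so every w is positive. Stop
codons and the single-codon families ATG and TGG carry no usage information
and are excluded from both the weights and the geometric mean; an internal
stop codon is excluded with a logged warning. CAI is exp(mean log w) over
the remaining codons, hence CAI = 1 exactly when every counted codon is
family-maximal, and CAI is invariant to codon order within a gene. Scale
invariance of the weights (duplicating the reference set changes nothing)
holds exactly for observed codons; unobserved codons keep a depth-dependent
pseudo-count weight by construction.

Per-species standardisation uses the sample (n−1) standard deviation. Group
comparisons default to the pooled-variance two-sample t-test ("Student"),
with Welch behind a flag. The pipeline's pre/post-WGD contrast compares
**per-species means of standardised CAI** between species groups; both raw
and standardised means are emitted since "average CAI" is ambiguous between
the two.

## Expression and fitness

Classification at condition *c*: down iff log2 ratio ≤ −log2(fold), up iff
≥ +log2(fold) (inclusive boundaries; "by 1.5-fold" is boundary-ambiguous and
the inclusive reading is tested explicitly), else unchanged; missing values
are unchanged with a logged warning. The motif association is a two-sided
Fisher's exact test on [[down_with, up_with], [down_without, up_without]],
reported with each group's down/up ratio. Correlations are Pearson by
default (Spearman behind a flag) over pairwise-complete observations; pairs
sharing fewer than 3 conditions are skipped and logged. A complete matrix
takes a single `corrcoef` fast path, required at compendium scale (~10³
conditions, ~10⁴ gene pairs). Deletion fitness is compared between motif
groups per condition with the two-tailed t-test.

## Synthetic data generator

The generator defines the study conditions; its defaults are the demo
study: two clades × five species, 1,000 genes per species of which 300 are
mitochondrial, mitochondrial motif rates 0.5 (saccharomycotina-like) vs 0.1
(outgroup), background rate 0.05, per-species GC spanning 0.35–0.42 and
0.45–0.56, ortholog presence 0.9, 1,011 expression conditions (the
compendium shape), within-block correlation ρ = 0.5, fermentative down-shift
δ = 1.0 on a marginal s.d. of 0.5, deletion-fitness effect of 1 s.d. in the
non-fermentative condition only.

Design choices that matter:

- **Planting overwrites bases in place** (an admitted 8-mer at a uniform
  admissible start within the first 250 bp), preserving length and window
  geometry.
- **Conservation structure**: a "core" subset (40%) of mitochondrial genes
  carries the motif at 1.8× the clade rate (capped at 1; the remainder
  absorbs the difference so the clade mean is exact) and belongs to the
  mitochondrial-translation set with probability 0.8 versus 0.04 outside
  the core. Ranking by conservation therefore produces the high-to-low
  translation-fraction gradient (~80% top, ~4% bottom) the conservation
  stage measures.
- **Codon bias** is a per-gene mixture parameter b (clipped N(0.5, 0.15);
  ribosomal reference genes at 0.9): each codon is its family's preferred
  codon with probability b, else uniform within the family. CAI is convex
  in b, so the requested `cai_z_shift` (default −0.5) is realised by
  numerically solving the deterministic b→CAI map for the bias shift whose
  mean CAI change equals the requested multiple of the deterministic CAI
  s.d. The empirical CAI s.d. remains somewhat inflated by reference-weight
  estimation noise and finite gene length, so the realised z-shift is
  attenuated (≈ −0.33 for a requested −0.5 under the validation design);
  the validation design (6 pre- + 6 post-WGD species, 160 mitochondrial
  genes, 150 codons, 40 reference genes) detects it with a large margin.
- **Expression**: block genes share one latent factor per condition
  (pairwise correlation exactly ρ), except the fermentative condition,
  whose noise is independent so the planted down-regulation is a
  deterministic condition mean rather than a random factor draw — with the
  factor loading on it, the realised shift would be −δ ± σ√ρ·u for a single
  shared draw u, erasing the effect in a material fraction of seeds.
- **Seeding**: all randomness flows from one master seed through spawned
  per-stage/per-species streams, so any species or stage is independently
  reproducible and the whole bundle is byte-stable.

What the generator does **not** emulate: phylogenetic correlation between
species (species are independent draws, so cross-species tests see more
effective replication than related genomes would provide), indels and
sequence evolution, UTR length variation and cleavage-site structure,
duplicate-gene retention beyond clade labels, microarray normalisation
artefacts, and missing data in expression (supported by the analysis code,
not planted by default). Passing tests therefore demonstrate statistical
correctness and power of the methods under their own assumptions, not
performance on real genomes.

## Problem sizes and numerical conventions

Validation runs are scaled to what the properties need: the scanner oracle
uses 1,000 sequences per GC level; the closed-form null check 10,000
sequences; the type-I error check 200 replicate species of 500 genes
against fresh per-species 2,000-sequence nulls (a shared null would
correlate outcomes across species and break the binomial bound); the
planted-enrichment recovery 50 replicates of 1,000 genes against
10,000-sequence nulls; the pipeline determinism check runs the full demo
twice at 10,000-sequence nulls. p-values are written in scientific notation
with 12 digits; other floats use full repr so TSV round-trips are exact.
The run manifest records the configuration (including its own output path),
the master seed, a config hash and per-stage row counts; determinism means
byte-identical result tables, with manifests equal up to the output path
they record.

## Known limitations

- The hypergeometric/Fisher machinery treats motif occurrences as
  exchangeable units; clustered occurrences within one gene are counted,
  not modelled.
- Only Bonferroni is wired into the result tables; other multiple-testing
  procedures would need to be applied downstream.
- The GC-matched null is zeroth-order; dinucleotide (Markov) backgrounds
  are out of scope by design.
- The cross-clade and pre/post-WGD t-tests treat species as independent
  replicates; with real genomes a phylogenetic correction would be needed.
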