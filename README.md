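# puf3regulon

Comparative analysis of the **Puf3p post-transcriptional regulon** across
fungal species: scanning 3′ downstream regions for the Puf3p-binding element
(P3E), testing its positional enrichment against GC-matched random
backgrounds, calling target genes, transferring subcellular-localization
annotations through orthology, profiling cross-species conservation of the
target state, contrasting codon adaptation between gene groups and clades,
and quantifying co-expression and deletion-fitness effects of motif-bearing
genes. The whole pipeline is exercised end-to-end on seedable synthetic
multi-species data, so every statistical property can be validated without
any genome downloads.

It is written for computational biologists studying RNA-binding-protein
regulons, 3′ UTR motif evolution, or codon-usage bias, either as a library
(`import puf3regulon`) or through the `puf3regulon` command line.

## The method

**Motif model.** The P3E core is an 8-nt element with seven invariant
positions and one flexible (fifth) position; the default profile string is
`TGTANATA` (DNA sense strand of the UGUA-N-AUA core, `N` = any base), and any
8-symbol profile over `{A,C,G,T,N}` can be substituted. Scanning is
sense-strand only and reports all (possibly overlapping) match offsets in
each gene's 3′ downstream region (up to 1,000 bp after the stop codon).

**Windowed enrichment.** Matches are pooled into 50-bp windows by start
offset, counting multiple occurrences per window as independent events. For
each species, 10,000 random 1,000-bp sequences are generated at the species'
own downstream GC content, with bases i.i.d. under
P(G) = P(C) = gc/2, P(A) = P(T) = (1 − gc)/2 (alternative backgrounds:
GC of the first 250 bp, or per-window GC). Per window *w*, enrichment is
tested with a one-sided Fisher's exact test on motif starts *k* out of
eligible start positions *n*:

    p_w = P(X ≥ k_obs),   X ~ Hypergeom(n_obs + n_null, k_obs + k_null, n_obs)

Bonferroni-corrected over the 20 windows (optionally over all species).
Genes with a complete match inside the first 250 bp (0-based start ≤ 242)
are called Puf3p targets.

**Downstream analyses.** Targets are tested for enrichment in each
localization category with the upper-tail hypergeometric test
(Bonferroni-corrected); per-species fractions of mitochondrial genes that
are targets are compared between clades by a two-sample t-test. A
conservation matrix (ortholog groups × species; target / present-non-target
/ ortholog-absent) is ranked by the fraction of non-absent cells that are
targets, and the mitochondrial-translation fraction is profiled in a 50-gene
sliding window down that ranking. Codon adaptation index per gene is the
geometric mean of relative adaptiveness values

    w(c) = count(c) / max count in the synonymous family

computed from the pooled ribosomal-protein reference set (unobserved codons
count 0.5; stop codons, ATG and TGG excluded), standardized to mean 0 / s.d.
1 within each species, and compared between pre- and post-WGD species by a
pooled two-sample t-test. Expression log2 ratios are classified as
down/up-regulated at a 1.5-fold threshold and associated with motif status
by a two-sided Fisher's exact test; co-regulation is the distribution of
pairwise Pearson correlations within and between the motif groups.

## Worked example

Simulate the demo study (two clades × five species; mitochondrial motif
rates 0.5 vs 0.1; 1,000 genes per species, 300 mitochondrial) and run every
stage:

```console
$ puf3regulon simulate --seed 1 --out demo_inputs
wrote bundle for 10 species to demo_inputs
$ puf3regulon all --input-dir demo_inputs --out demo_results --seed 1
wrote 18 result table(s) to demo_results
```

`demo_results/mito_fractions.tsv` shows the clade contrast the study design
plants — about half of mitochondrial genes are targets in the
saccharomycotina-like clade, ~10% in the outgroup:

```
species_id	mito_target_fraction	clade
outgroup_s01	0.12359550561797752	outgroup
...
saccharomycotina_s01	0.5186567164179104	saccharomycotina
...
```

and `clade_comparison.tsv` quantifies it (t = −36.4, p = 3.6e−10 across the
ten species). `gc_regression.tsv` recovers the negative relationship between
downstream GC content and the number of motif-bearing genes:

```
slope	intercept	r_squared	p_value	n_species
-882.1303880989665	526.6217383881399	0.83629636170968	2.107281473618e-04	10
```

`window_enrichment.tsv` holds the per-species, per-window Fisher results
(observed vs null counts, raw and Bonferroni p, significance flag);
enrichment concentrates in the windows covering the first 250 bp, the span
that approximates the yeast 3′ UTR. `regulation_association.tsv` shows the
planted fermentative down-regulation of motif-bearing mitochondrial genes
(down/up ratio 50.5 vs 0.93, Fisher p = 8.8e−10), and
`correlation_comparison.tsv` their elevated co-expression (mean pairwise
r = 0.40 vs −0.00 for motif-free genes).

The same stages are available individually (`scan`, `null`,
`enrich-windows`, `enrich-categories`, `conserve`, `cai`, `expr`,
`fitness`), each reading/writing plain TSV.

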