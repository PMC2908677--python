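"""Localization-category enrichment of Puf3p targets, transferred via orthology.

Species genes inherit the subcellular compartment of their reference-species
orthologs; per compartment, an upper-tail hypergeometric test asks whether
called targets are over-represented relative to the genome, with Bonferroni
correction over the compartments tested.  A cross-clade comparison contrasts
the per-species fraction of mitochondrial genes that are targets.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationTable, OrthologMap
from .motif import TargetSet


def map_categories(
    orthologs: OrthologMap,
    annotations: AnnotationTable,
    policy: str = "all",
) -> dict[str, set[str]]:
    """species gene -> set of inherited compartment labels.

    Genes without an annotated ortholog are absent from the result (they stay
    in the genome background but join no category).  With ``policy="all"`` a
    gene with several annotated orthologs keeps every compartment; with
    ``"best"`` only the lexicographically first reference gene's compartment
    is kept (a deterministic single-membership tie-break).
    """
    if policy not in ("all", "best"):
        raise ValueError(f"policy must be 'all' or 'best', got {policy!r}")
    out: dict[str, set[str]] = {}
    for sp_gene, ref_genes in orthologs.by_species_gene().items():
        annotated = sorted(r for r in ref_genes if r in annotations.localization)
        if not annotated:
            continue
        if policy == "best":
            annotated = annotated[:1]
        out[sp_gene] = {annotations.localization[r] for r in annotated}
    return out


def category_test(
    targets: TargetSet,
    categories: Mapping[str, set[str]],
    genome: set[str],
    alpha: float = 0.01,
    background: str = "all",
) -> pd.DataFrame:
    """Hypergeometric enrichment of targets in each localization category.

    Per category: p = P(X >= n_category_targets) for X drawn as
    ``n_category`` genes from ``n_genome`` with ``n_genome_targets``
    successes; Bonferroni over categories.  ``background="all"`` uses every
    gene with a scanned downstream region; ``"annotated"`` restricts the
    genome to genes with an inherited compartment.
    """
    if not categories:
        raise ValueError("no categories to test")
    if background not in ("all", "annotated"):
        raise ValueError(f"background must be 'all' or 'annotated', got {background!r}")
    bg = set(genome) if background == "all" else (set(genome) & set(categories))
    target_bg = targets.targets & bg
    n_genome = len(bg)
    n_genome_targets = len(target_bg)

    by_compartment: dict[str, set[str]] = {}
    for gene, comps in categories.items():
        if gene not in bg:
            continue
        for comp in comps:
            by_compartment.setdefault(comp, set()).add(gene)

    m = len(by_compartment)
    rows = []
    for comp in sorted(by_compartment):
        members = by_compartment[comp]
        n_cat = len(members)
        if n_cat > n_genome:
            raise ValueError(f"category {comp!r} larger than genome background")
        n_cat_targets = len(members & target_bg)
        p_raw = float(stats.hypergeom.sf(n_cat_targets - 1, n_genome, n_genome_targets, n_cat))
        p_bonf = min(1.0, p_raw * m)
        rows.append(
            {
                "species_id": targets.species_id,
                "category": comp,
                "n_category": n_cat,
                "n_category_targets": n_cat_targets,
                "n_genome": n_genome,
                "n_genome_targets": n_genome_targets,
                "p_raw": p_raw,
                "p_bonferroni": p_bonf,
                "significant": p_bonf < alpha,
            }
        )
    return pd.DataFrame(rows)


def category_target_fraction(
    targets: TargetSet, categories: Mapping[str, set[str]], compartment: str
) -> float:
    """Fraction of genes in one compartment that are called targets."""
    members = {g for g, comps in categories.items() if compartment in comps}
    if not members:
        raise ValueError(f"no genes in compartment {compartment!r}")
    return len(members & targets.targets) / len(members)


def clade_fraction_compare(
    fractions: Mapping[str, float],
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
) -> tuple[float, float]:
    """Two-sample two-tailed t-test on per-species target fractions.

    ``fractions`` maps species -> fraction (e.g. of mitochondrial genes that
    are targets); ``groups`` maps species -> clade label.
    """
    a = [fractions[s] for s in sorted(fractions) if groups.get(s) == group_a]
    b = [fractions[s] for s in sorted(fractions) if groups.get(s) == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each clade needs at least 2 species")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0  # identical constant groups: no difference
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)
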