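"""Codon adaptation index (CAI) against a ribosomal-protein reference set.

Relative adaptiveness w(c) of a codon is its count in the pooled reference
CDS divided by the count of the most-used codon of the same synonymous
family; codons unobserved in the reference receive a count of 0.5 before
normalisation.  Stop codons and the single-codon families ATG (Met) and TGG
(Trp) carry no usage information and are excluded throughout.  A gene's CAI
is the geometric mean of w over its remaining codons, so CAI is 1 exactly
when every counted codon is family-maximal.

To compare codon bias across species with different compositional baselines,
per-species CAI values are standardised to mean 0 and (sample) standard
deviation 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)

#: synonymous families with >= 2 codons (amino acid -> codons); Met and Trp excluded
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _STANDARD.forward_table.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)
SYNONYMOUS_FAMILIES = {
    aa: tuple(sorted(codons)) for aa, codons in SYNONYMOUS_FAMILIES.items() if len(codons) >= 2
}
SINGLE_CODONS = frozenset({"ATG", "TGG"})
EXCLUDED_CODONS = STOP_CODONS | SINGLE_CODONS
_FAMILY_OF = {c: aa for aa, codons in SYNONYMOUS_FAMILIES.items() for c in codons}


@dataclass
class AdaptivenessTable:
    """Per-codon relative adaptiveness w in (0, 1] from a reference gene set."""

    w: dict[str, float]
    reference_gene_count: int
    excluded_codons: frozenset[str] = EXCLUDED_CODONS

    def __post_init__(self) -> None:
        for codon, value in self.w.items():
            if not 0 < value <= 1:
                raise ValueError(f"w({codon}) = {value} outside (0, 1]")


def iter_codons(cds: str) -> Iterable[str]:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    for i in range(0, len(cds), 3):
        yield cds[i : i + 3]


def reference_weights(reference_cds: Sequence[str]) -> AdaptivenessTable:
    """Relative adaptiveness from codon counts pooled over the reference CDS.

    All gene copies are pooled regardless of copy number.  Within each
    synonymous family, w(c) = count(c) / max count; zero counts become 0.5
    first, so every w is strictly positive.
    """
    if not reference_cds:
        raise ValueError("reference set is empty")
    counts: dict[str, float] = {c: 0.0 for c in _FAMILY_OF}
    for cds in reference_cds:
        for codon in iter_codons(cds):
            if codon in counts:
                counts[codon] += 1.0
    w: dict[str, float] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        fam = {c: (counts[c] if counts[c] > 0 else 0.5) for c in codons}
        top = max(fam.values())
        for c in codons:
            w[c] = fam[c] / top
    return AdaptivenessTable(w=w, reference_gene_count=len(reference_cds))


def cai(cds: str, table: AdaptivenessTable) -> float:
    """Geometric mean of w over the gene's codons (stops, ATG, TGG excluded).

    A stop codon before the final position is excluded from the product like
    any other stop, with a logged warning.
    """
    log_sum = 0.0
    n = 0
    codons = list(iter_codons(cds))
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            if i < len(codons) - 1:
                logger.warning("internal stop codon %s at codon %d; excluded from CAI", codon, i)
            continue
        if codon in SINGLE_CODONS or codon not in table.w:
            continue  # no usage information (or ambiguous bases)
        log_sum += math.log(table.w[codon])
        n += 1
    if n == 0:
        raise ValueError("no countable codons after exclusions")
    return math.exp(log_sum / n)


def cai_table(cds_map: Mapping[str, str], table: AdaptivenessTable) -> dict[str, float]:
    """CAI for every gene of a species."""
    return {gene: cai(cds, table) for gene, cds in cds_map.items()}


def standardize(values: Sequence[float]) -> np.ndarray:
    """z-scores with sample (n-1) standard deviation; mean 0, sd 1 by construction."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("standardization needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; standardization undefined")
    return (x - x.mean()) / sd


def group_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample two-tailed t-test (pooled variance by default, Welch optional)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
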