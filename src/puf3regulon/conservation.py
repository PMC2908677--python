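"""Cross-species conservation of the Puf3p target state per ortholog group.

Each reference gene (ortholog group) gets one row; each species one column.
A cell is ``target`` when any ortholog of the gene in that species is a
called target, ``present_nontarget`` when orthologs exist but none is a
target, and ``absent`` when the species has no ortholog.  The row score is
the fraction of non-absent cells that are targets — conservation among
orthologs, not among species — and rows are ranked by it (ties broken by
gene id so output is byte-reproducible).

Along that ranking, a sliding window (default 50 genes, step 1) reports the
fraction of window genes belonging to a function set such as mitochondrial
translation; in a conserved regulon this fraction decays from top to bottom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import OrthologMap
from .motif import TargetSet

logger = logging.getLogger(__name__)

STATE_TARGET = "target"
STATE_PRESENT = "present_nontarget"
STATE_ABSENT = "absent"
_STATE_CODES = {STATE_TARGET: "T", STATE_PRESENT: "P", STATE_ABSENT: "A"}


@dataclass
class ConservationMatrix:
    """Ortholog groups x species state matrix with per-row conservation scores."""

    states: pd.DataFrame  # rows: reference genes, cols: species ids, values: states
    row_score: pd.Series  # fraction of non-absent cells that are target

    @property
    def genes(self) -> list[str]:
        return list(self.states.index)

    @property
    def species(self) -> list[str]:
        return list(self.states.columns)

    def to_letters(self) -> pd.DataFrame:
        """Compact T/P/A rendering for TSV output."""
        return self.states.replace(_STATE_CODES)


def build_matrix(
    gene_set: set[str],
    per_species: Mapping[str, tuple[TargetSet, OrthologMap]],
) -> ConservationMatrix:
    """Assemble the conservation matrix over ``gene_set`` reference genes.

    Rows whose gene is absent from every species carry no information and are
    dropped with a warning.  Rows are sorted by descending conservation score,
    then gene id.
    """
    if not gene_set:
        raise ValueError("gene_set is empty")
    species_ids = sorted(per_species)
    genes = sorted(gene_set)
    data: dict[str, list[str]] = {}
    for sp in species_ids:
        targets, orthologs = per_species[sp]
        ref_to_sp = orthologs.by_reference_gene()
        col = []
        for gene in genes:
            sp_genes = ref_to_sp.get(gene, set())
            if not sp_genes:
                col.append(STATE_ABSENT)
            elif sp_genes & targets.targets:
                col.append(STATE_TARGET)
            else:
                col.append(STATE_PRESENT)
        data[sp] = col
    states = pd.DataFrame(data, index=genes)

    present = states != STATE_ABSENT
    n_present = present.sum(axis=1)
    dropped = states.index[n_present == 0]
    if len(dropped):
        logger.warning("dropping %d gene(s) absent from every species: %s",
                       len(dropped), ", ".join(dropped[:5]))
        states = states.loc[n_present > 0]
        n_present = n_present[n_present > 0]
    n_target = (states == STATE_TARGET).sum(axis=1)
    score = n_target / n_present

    order = sorted(states.index, key=lambda g: (-score[g], g))
    states = states.loc[order]
    return ConservationMatrix(states=states, row_score=score.loc[order])


def sliding_function_fraction(
    matrix: ConservationMatrix,
    function_set: set[str],
    window: int = 50,
    step: int = 1,
) -> pd.DataFrame:
    """Function-set fraction in sliding windows down the conservation ranking.

    Returns one row per window with its rank span and the fraction of its
    genes in ``function_set``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    genes = matrix.genes
    if window > len(genes):
        raise ValueError(f"window {window} exceeds number of rows {len(genes)}")
    member = np.array([g in function_set for g in genes], dtype=float)
    rows = []
    for start in range(0, len(genes) - window + 1, step):
        rows.append(
            {
                "rank_start": start,
                "rank_end": start + window,
                "fraction": float(member[start : start + window].mean()),
            }
        )
    return pd.DataFrame(rows)
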