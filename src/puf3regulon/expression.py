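"""Expression-change classification and co-regulation of motif-bearing genes.

Under the fermentative condition, genes are classified as down- or
up-regulated when their log2 expression ratio to the reference pool is at
least ``log2(fold)`` in magnitude (default fold 1.5, inclusive boundary).
A two-sided Fisher's exact test asks whether down/up counts differ between
motif-bearing and motif-free gene groups; the plotted statistic is each
group's down/up ratio.

Co-regulation is quantified by the distributions of pairwise Pearson
correlation coefficients across conditions — within each group and between
groups — compared with a two-sample t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class RegulationCounts:
    """Down / up / unchanged tallies for one gene group at one condition."""

    group: str
    n_down: int
    n_up: int
    n_unchanged: int
    threshold: float = 1.5

    @property
    def size(self) -> int:
        return self.n_down + self.n_up + self.n_unchanged

    @property
    def down_up_ratio(self) -> float:
        if self.n_up == 0:
            return math.inf if self.n_down > 0 else math.nan
        return self.n_down / self.n_up


@dataclass
class AssociationResult:
    odds_ratio: float
    pvalue: float
    ratio_with: float
    ratio_without: float
    table: tuple[tuple[int, int], tuple[int, int]]


def classify_regulation(
    matrix: pd.DataFrame,
    condition: str,
    fold: float = 1.5,
    genes: Iterable[str] | None = None,
    group: str = "all",
) -> RegulationCounts:
    """Classify each gene's log2 ratio at one condition by the fold threshold.

    down iff log2 ratio <= -log2(fold); up iff >= +log2(fold); otherwise
    unchanged.  Missing values count as unchanged, with a logged warning.
    """
    if condition not in matrix.columns:
        raise ValueError(f"unknown condition {condition!r}; have {list(matrix.columns)[:5]}...")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    gene_list = list(genes) if genes is not None else list(matrix.index)
    missing_genes = [g for g in gene_list if g not in matrix.index]
    if missing_genes:
        raise ValueError(f"genes not in expression matrix: {missing_genes[:5]}")
    values = matrix.loc[gene_list, condition]
    cut = math.log2(fold)
    n_missing = int(values.isna().sum())
    if n_missing:
        logger.warning("%d missing value(s) at %s treated as unchanged", n_missing, condition)
    n_down = int((values <= -cut).sum())
    n_up = int((values >= cut).sum())
    return RegulationCounts(
        group=group,
        n_down=n_down,
        n_up=n_up,
        n_unchanged=len(gene_list) - n_down - n_up,
        threshold=fold,
    )


def regulation_association(
    counts_with: RegulationCounts, counts_without: RegulationCounts
) -> AssociationResult:
    """Two-sided Fisher's exact test on [[down_with, up_with], [down_without, up_without]]."""
    table = (
        (counts_with.n_down, counts_with.n_up),
        (counts_without.n_down, counts_without.n_up),
    )
    if counts_with.n_down + counts_with.n_up == 0 or counts_without.n_down + counts_without.n_up == 0:
        raise ValueError("a group has no regulated (down+up) genes; association undefined")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return AssociationResult(
        odds_ratio=float(odds),
        pvalue=float(p),
        ratio_with=counts_with.down_up_ratio,
        ratio_without=counts_without.down_up_ratio,
        table=table,
    )


def _pairwise_correlations(
    matrix: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    method: str = "pearson",
    min_overlap: int = 3,
) -> np.ndarray:
    values = matrix.to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(matrix.index)}
    out = []
    n_skipped = 0
    for g1, g2 in pairs:
        x, y = values[index[g1]], values[index[g2]]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < min_overlap:
            n_skipped += 1
            continue
        if method == "pearson":
            r = stats.pearsonr(x[ok], y[ok]).statistic
        elif method == "spearman":
            r = stats.spearmanr(x[ok], y[ok]).statistic
        else:
            raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
        out.append(float(r))
    if n_skipped:
        logger.warning("skipped %d pair(s) with < %d shared conditions", n_skipped, min_overlap)
    return np.asarray(out, dtype=float)


def pairwise_correlation_distributions(
    matrix: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    method: str = "pearson",
    min_overlap: int = 3,
) -> dict[str, np.ndarray]:
    """Correlation coefficient distributions within and between two gene groups.

    Returns ``{"within_a": ..., "within_b": ..., "between": ...}`` over all
    unordered within-group pairs and all between-group pairs, using
    pairwise-complete observations.  Pairs sharing fewer than ``min_overlap``
    conditions are skipped and logged.
    """
    a = sorted(set(group_a))
    b = sorted(set(group_b))
    missing = [g for g in a + b if g not in matrix.index]
    if missing:
        raise ValueError(f"genes not in expression matrix: {missing[:5]}")
    overlap = set(a) & set(b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    sub = matrix.loc[a + b]
    if method == "pearson" and not sub.isna().any().any() and sub.shape[1] >= min_overlap:
        # complete matrix: one corrcoef call instead of per-pair loops
        corr = np.corrcoef(sub.to_numpy(dtype=float))
        n_a = len(a)
        iu_a = np.triu_indices(n_a, k=1)
        iu_b = np.triu_indices(len(b), k=1)
        return {
            "within_a": corr[:n_a, :n_a][iu_a],
            "within_b": corr[n_a:, n_a:][iu_b],
            "between": corr[:n_a, n_a:].ravel(),
        }
    return {
        "within_a": _pairwise_correlations(matrix, list(combinations(a, 2)), method, min_overlap),
        "within_b": _pairwise_correlations(matrix, list(combinations(b, 2)), method, min_overlap),
        "between": _pairwise_correlations(matrix, [(x, y) for x in a for y in b], method, min_overlap),
    }


def compare_distributions(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample two-tailed t-test between two correlation distributions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each distribution needs at least 2 values")
    t, p = stats.ttest_ind(x, y)
    return float(t), float(p)
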