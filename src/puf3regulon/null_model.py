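"""GC-matched random-sequence null model and per-window enrichment tests.

Chance occurrence of the AT-rich P3E depends strongly on base composition,
so observed window counts are compared against random sequences generated at
the species' own GC content.  Three background dialects are supported:

``full_region``
    one GC fraction pooled over the whole 1,000 bp downstream region of all
    genes (the default);
``utr250``
    GC pooled over the first 250 bp after the stop codon;
``per_window``
    a separate GC fraction per 50-bp window, each window of the random
    sequences drawn at its own composition.

Random bases are i.i.d. with the symmetric decomposition
P(G) = P(C) = gc/2, P(A) = P(T) = (1-gc)/2.  Per window, the observed motif
starts out of observed eligible start positions are compared to the null
counts with a one-sided (greater) Fisher's exact test — only enrichment is
interpreted — and Bonferroni-corrected over the windows tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SpeciesDataset
from .motif import (
    DEFAULT_REGION,
    DEFAULT_UTR_CUTOFF,
    DEFAULT_WINDOW,
    MOTIF_LENGTH,
    MotifProfile,
    WindowCounts,
    call_targets,
    hit_matrix,
    windows_from_hits,
)

GC_MODES = ("full_region", "utr250", "per_window")

_CODE_A, _CODE_C, _CODE_G, _CODE_T = 0, 1, 2, 3


@dataclass
class GCModel:
    """Background base composition: scalar GC, or one value per window."""

    mode: str
    gc: float | np.ndarray
    window_size: int = DEFAULT_WINDOW
    region_length: int = DEFAULT_REGION

    def __post_init__(self) -> None:
        if self.mode not in GC_MODES:
            raise ValueError(f"mode must be one of {GC_MODES}, got {self.mode!r}")
        gc = np.asarray(self.gc, dtype=float)
        if np.any(gc < 0) or np.any(gc > 1):
            raise ValueError("gc must lie in [0, 1]")
        if self.mode == "per_window":
            n_windows = self.region_length // self.window_size
            if gc.shape != (n_windows,):
                raise ValueError(f"per_window gc must have length {n_windows}")


@dataclass
class NullCounts:
    """Window counts measured on the random-sequence background."""

    n_sequences: int
    seq_length: int
    seed: int
    counts: WindowCounts


def estimate_gc(
    dataset: SpeciesDataset,
    mode: str = "full_region",
    window_size: int = DEFAULT_WINDOW,
    region_length: int = DEFAULT_REGION,
) -> GCModel:
    """Pooled GC fraction of a species' downstream regions.

    gc = (#G + #C) / (#A + #C + #G + #T); N is excluded from both numerator
    and denominator.
    """
    if mode not in GC_MODES:
        raise ValueError(f"mode must be one of {GC_MODES}, got {mode!r}")
    if not dataset.downstream:
        raise ValueError(f"{dataset.species_id}: no downstream sequences")

    if mode == "per_window":
        n_windows = region_length // window_size
        gc_counts = np.zeros(n_windows, dtype=np.int64)
        at_counts = np.zeros(n_windows, dtype=np.int64)
        for seq in dataset.downstream.values():
            for w in range(n_windows):
                chunk = seq[w * window_size : (w + 1) * window_size]
                if not chunk:
                    break
                gc_counts[w] += chunk.count("G") + chunk.count("C")
                at_counts[w] += chunk.count("A") + chunk.count("T")
        totals = gc_counts + at_counts
        if np.any(totals == 0):
            raise ValueError("a window has zero countable bases; cannot estimate per-window GC")
        return GCModel(mode=mode, gc=gc_counts / totals, window_size=window_size, region_length=region_length)

    limit = 250 if mode == "utr250" else region_length
    gc_n = at_n = 0
    for seq in dataset.downstream.values():
        chunk = seq[:limit]
        gc_n += chunk.count("G") + chunk.count("C")
        at_n += chunk.count("A") + chunk.count("T")
    if gc_n + at_n == 0:
        raise ValueError("zero countable bases (all N?); cannot estimate GC")
    return GCModel(mode=mode, gc=gc_n / (gc_n + at_n), window_size=window_size, region_length=region_length)


def random_base_codes(gc: float | np.ndarray, n: int, length: int, rng: np.random.Generator,
                      window_size: int = DEFAULT_WINDOW) -> np.ndarray:
    """(n, length) uint8 base codes drawn i.i.d. from the GC model.

    Scalar ``gc`` applies everywhere; a vector gives each ``window_size``
    block its own composition.
    """
    gc_arr = np.asarray(gc, dtype=float)
    u = rng.random((n, length))
    if gc_arr.ndim == 0:
        per_pos_gc = np.full(length, float(gc_arr))
    else:
        per_pos_gc = np.repeat(gc_arr, window_size)[:length]
        if len(per_pos_gc) < length:
            per_pos_gc = np.pad(per_pos_gc, (0, length - len(per_pos_gc)), mode="edge")
    # cumulative probabilities over base order A, C, G, T
    p_a = (1 - per_pos_gc) / 2
    p_c = per_pos_gc / 2
    c1 = p_a
    c2 = p_a + p_c
    c3 = p_a + 2 * p_c
    codes = np.zeros((n, length), dtype=np.uint8)
    codes[u >= c1] = _CODE_C
    codes[u >= c2] = _CODE_G
    codes[u >= c3] = _CODE_T
    return codes


def generate_null(
    gc_model: GCModel,
    profile: MotifProfile,
    n: int = 10_000,
    length: int = DEFAULT_REGION,
    seed: int = 0,
    window_size: int = DEFAULT_WINDOW,
) -> NullCounts:
    """Scan ``n`` random sequences of ``length`` bp drawn from the GC model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    codes = random_base_codes(gc_model.gc, n, length, rng, window_size=gc_model.window_size)
    lengths = np.full(n, length, dtype=np.int64)
    hits = hit_matrix(codes, lengths, profile)
    counts = windows_from_hits(hits, lengths, window_size=window_size, region_length=gc_model.region_length)
    return NullCounts(n_sequences=n, seq_length=length, seed=seed, counts=counts)


def window_enrichment_test(
    observed: WindowCounts,
    null: NullCounts | WindowCounts,
    alpha: float = 0.01,
    bonferroni_n: int | None = None,
) -> pd.DataFrame:
    """Per-window one-sided Fisher's exact test of motif enrichment.

    The 2x2 unit is motif start positions vs eligible start positions
    (pooled over genes / random sequences), which respects counting multiple
    occurrences per window as independent events::

        [[obs_count,  obs_eligible  - obs_count ],
         [null_count, null_eligible - null_count]]

    The one-sided (greater) Fisher p equals the upper hypergeometric tail
    P(X >= obs_count) and is computed through it.  ``bonferroni_n`` defaults
    to the number of windows in this table; pass a larger value to correct
    across species.
    """
    null_counts = null.counts if isinstance(null, NullCounts) else null
    if (observed.window_size, observed.region_length) != (null_counts.window_size, null_counts.region_length):
        raise ValueError("observed and null window geometry differ")
    n_windows = observed.n_windows
    m = n_windows if bonferroni_n is None else bonferroni_n
    rows = []
    for w in range(n_windows):
        obs_c = int(observed.counts[w])
        obs_e = int(observed.eligible_positions[w])
        nul_c = int(null_counts.counts[w])
        nul_e = int(null_counts.eligible_positions[w])
        if obs_e < obs_c or nul_e < nul_c:
            raise ValueError(f"window {w}: eligible < count (corrupt counts)")
        total = obs_e + nul_e
        successes = obs_c + nul_c
        # P(X >= obs_c), X ~ Hypergeom(total, successes, draws=obs_e)
        p_raw = float(stats.hypergeom.sf(obs_c - 1, total, successes, obs_e)) if total else 1.0
        p_bonf = min(1.0, p_raw * m)
        rows.append(
            {
                "window_start": w * observed.window_size,
                "window_end": (w + 1) * observed.window_size,
                "obs_count": obs_c,
                "obs_eligible": obs_e,
                "null_count": nul_c,
                "null_eligible": nul_e,
                "p_raw": p_raw,
                "p_bonferroni": p_bonf,
                "significant": p_bonf < alpha,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    pvalue: float
    n: int


def gc_vs_target_regression(
    datasets: Sequence[SpeciesDataset],
    profile: MotifProfile,
    utr_cutoff: int = DEFAULT_UTR_CUTOFF,
) -> RegressionResult:
    """OLS of per-species motif-gene count on downstream GC fraction.

    The response is the number of genes with at least one P3E under the
    250-bp target rule; for an AT-rich profile the fitted slope is negative.
    """
    if len(datasets) < 3:
        raise ValueError("regression needs at least 3 species")
    gc = np.array([estimate_gc(ds, "full_region").gc for ds in datasets], dtype=float)
    counts = np.array(
        [len(call_targets(ds, profile, utr_cutoff=utr_cutoff).targets) for ds in datasets],
        dtype=float,
    )
    if np.allclose(gc, gc[0]):
        raise ValueError("zero variance in GC across species; regression undefined")
    fit = stats.linregress(gc, counts)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        pvalue=float(fit.pvalue),
        n=len(datasets),
    )


def expected_matches_per_window(profile: MotifProfile, gc: float, n_sequences: int,
                                length: int = DEFAULT_REGION,
                                window_size: int = DEFAULT_WINDOW) -> np.ndarray:
    """Closed-form expected null counts per window: eligible starts x match prob."""
    p = profile.match_probability(gc)
    lengths = np.full(n_sequences, length, dtype=np.int64)
    from .motif import _eligible_per_window

    eligible = _eligible_per_window(lengths, window_size, length)
    return eligible * p
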