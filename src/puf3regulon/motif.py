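"""Puf3p-binding-element (P3E) scanning and windowed match counting.

The P3E core is an 8-nt element with seven invariant positions and one
flexible (fifth) position.  A :class:`MotifProfile` stores, per position, the
set of admitted nucleotides; the default profile is ``TGTANATA`` (the DNA
sense strand of the UGUA-N-AUA core, N = any base).  Scanning is sense-strand
only — the element is read on the mRNA — and overlapping matches are all
reported.

Matches are aggregated by the 0-based start offset into fixed windows
(default 50 bp over a 1,000 bp region); multiple matches in one window count
as independent events.  A gene is called a Puf3p target when a full match
lies within the first ``utr_cutoff`` bases after the stop codon (default
250 bp, the span that approximates the yeast 3' UTR): 0-based start
``<= utr_cutoff - 8``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import SpeciesDataset

MOTIF_LENGTH = 8
DEFAULT_PROFILE = "TGTANATA"
DEFAULT_WINDOW = 50
DEFAULT_REGION = 1000
DEFAULT_UTR_CUTOFF = 250

_BASES = "ACGT"
_CODE = {c: i for i, c in enumerate("ACGTN")}
_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)  # unknown -> N (never matches)
for _c, _i in _CODE.items():
    _ENCODE_TABLE[ord(_c)] = _i


@dataclass(frozen=True)
class MotifProfile:
    """Ordered per-position nucleotide constraints of an 8-nt element."""

    positions: tuple[frozenset[str], ...]
    name: str = "P3E"

    def __post_init__(self) -> None:
        if len(self.positions) != MOTIF_LENGTH:
            raise ValueError(f"profile must have {MOTIF_LENGTH} positions, got {len(self.positions)}")
        for i, allowed in enumerate(self.positions):
            if not allowed or not allowed <= set(_BASES):
                raise ValueError(f"position {i}: allowed set {sorted(allowed)} invalid")

    @property
    def length(self) -> int:
        return len(self.positions)

    def admitted_words(self) -> list[str]:
        """All 8-mers the profile matches (cartesian product of the sets)."""
        words = [""]
        for allowed in self.positions:
            words = [w + c for w in words for c in sorted(allowed)]
        return words

    def allowed_mask(self) -> np.ndarray:
        """(8, 5) boolean lookup over base codes A,C,G,T,N; N never matches."""
        mask = np.zeros((MOTIF_LENGTH, 5), dtype=bool)
        for i, allowed in enumerate(self.positions):
            for c in allowed:
                mask[i, _CODE[c]] = True
        return mask

    def match_probability(self, gc: float) -> float:
        """P(an i.i.d. base window matches) under P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
        base_p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
        p = 1.0
        for allowed in self.positions:
            p *= sum(base_p[c] for c in allowed)
        return p


def compile_profile(spec: str, name: str = "P3E") -> MotifProfile:
    """Compile an 8-symbol string over {A,C,G,T,N} into a profile.

    ``N`` expands to all four nucleotides (a flexible position); any letter
    becomes a singleton constraint.  The default ``"TGTANATA"`` fixes seven
    sites and frees the fifth.
    """
    spec = spec.upper()
    if len(spec) != MOTIF_LENGTH:
        raise ValueError(f"profile spec must be {MOTIF_LENGTH} symbols, got {len(spec)} ({spec!r})")
    positions = []
    for sym in spec:
        if sym == "N":
            positions.append(frozenset(_BASES))
        elif sym in _BASES:
            positions.append(frozenset(sym))
        else:
            raise ValueError(f"invalid profile symbol {sym!r}; expected A/C/G/T/N")
    return MotifProfile(positions=tuple(positions), name=name)


@dataclass
class MatchList:
    """Sorted 0-based start offsets of motif matches within one downstream region."""

    gene_id: str
    starts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.starts, self.starts[1:])):
            raise ValueError(f"{self.gene_id}: starts must be strictly increasing")


@dataclass
class WindowCounts:
    """Motif occurrences and scannable start positions pooled per window."""

    window_size: int
    region_length: int
    counts: np.ndarray
    eligible_positions: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        n_windows = -(-self.region_length // self.window_size)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.eligible_positions = np.asarray(self.eligible_positions, dtype=np.int64)
        if len(self.counts) != n_windows or len(self.eligible_positions) != n_windows:
            raise ValueError(f"expected {n_windows} windows")
        if np.any(self.eligible_positions < self.counts):
            raise ValueError("eligible positions < counts: corrupt window counts")

    @property
    def n_windows(self) -> int:
        return len(self.counts)


@dataclass
class TargetSet:
    """Genes of one species with a P3E in their proximal 3' downstream region."""

    species_id: str
    targets: set[str]
    utr_cutoff: int = DEFAULT_UTR_CUTOFF


# ---------------------------------------------------------------------------
# encoding and vectorised scanning
# ---------------------------------------------------------------------------


def encode_sequences(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Pack sequences into a (n, max_len) uint8 code matrix padded with N."""
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    max_len = int(lengths.max()) if len(seqs) else 0
    codes = np.full((len(seqs), max_len), _CODE["N"], dtype=np.uint8)
    for row, s in enumerate(seqs):
        codes[row, : len(s)] = _ENCODE_TABLE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    return codes, lengths


def hit_matrix(codes: np.ndarray, lengths: np.ndarray, profile: MotifProfile) -> np.ndarray:
    """Boolean (n, max_len - 7) matrix: True where an 8-mer match starts.

    Positions whose window would run past a sequence's true end are False
    (the padding N matches nothing, which enforces this automatically).
    """
    n, max_len = codes.shape
    n_starts = max(max_len - MOTIF_LENGTH + 1, 0)
    if n == 0 or n_starts == 0:
        return np.zeros((n, 0), dtype=bool)
    mask = profile.allowed_mask()
    hits = mask[0][codes[:, :n_starts]]
    for k in range(1, MOTIF_LENGTH):
        hits &= mask[k][codes[:, k : k + n_starts]]
    return hits


def scan_sequence(seq: str, profile: MotifProfile) -> list[int]:
    """All 0-based offsets where ``seq`` matches the profile (overlaps included)."""
    if len(seq) < MOTIF_LENGTH:
        return []
    codes, lengths = encode_sequences([seq.upper()])
    return np.flatnonzero(hit_matrix(codes, lengths, profile)[0]).tolist()


def scan_dataset(dataset: SpeciesDataset, profile: MotifProfile) -> dict[str, MatchList]:
    """Scan every downstream region of a species; returns per-gene match lists."""
    genes = dataset.genes
    codes, lengths = encode_sequences([dataset.downstream[g] for g in genes])
    hits = hit_matrix(codes, lengths, profile)
    rows, cols = np.nonzero(hits)
    out = {g: MatchList(gene_id=g) for g in genes}
    for r, c in zip(rows.tolist(), cols.tolist()):
        out[genes[r]].starts.append(c)
    return out


def _eligible_per_window(lengths: np.ndarray, window_size: int, region_length: int) -> np.ndarray:
    """Per-window count of valid 8-mer start offsets summed over genes.

    A gene of length L contributes starts 0..min(L, region_length) - 8; the
    start falling in window ``floor(start / window_size)``.
    """
    n_windows = -(-region_length // window_size)
    eligible = np.zeros(n_windows, dtype=np.int64)
    capped = np.minimum(lengths, region_length)
    n_starts = np.maximum(capped - MOTIF_LENGTH + 1, 0)  # per-gene valid starts
    edges = np.arange(0, n_windows + 1) * window_size
    for w in range(n_windows):
        lo, hi = edges[w], edges[w + 1]
        eligible[w] = np.sum(np.clip(n_starts - lo, 0, hi - lo))
    return eligible


def count_in_windows(
    matches: Mapping[str, MatchList | Sequence[int]],
    lengths: Mapping[str, int],
    window_size: int = DEFAULT_WINDOW,
    region_length: int = DEFAULT_REGION,
) -> WindowCounts:
    """Pool per-gene match starts into fixed windows over the downstream region.

    A match is assigned to window ``floor(start / window_size)``; multiple
    matches in one window are independent events.  Matches starting at or
    beyond ``region_length`` are ignored.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if region_length % window_size != 0:
        raise ValueError("window_size must divide region_length")
    n_windows = region_length // window_size
    counts = np.zeros(n_windows, dtype=np.int64)
    for gene, m in matches.items():
        starts = m.starts if isinstance(m, MatchList) else m
        for s in starts:
            if s < region_length:
                counts[s // window_size] += 1
    lens = np.fromiter((lengths[g] for g in matches), dtype=np.int64, count=len(matches))
    eligible = _eligible_per_window(lens, window_size, region_length)
    return WindowCounts(
        window_size=window_size,
        region_length=region_length,
        counts=counts,
        eligible_positions=eligible,
        n_genes=len(matches),
    )


def windows_from_hits(
    hits: np.ndarray,
    lengths: np.ndarray,
    window_size: int = DEFAULT_WINDOW,
    region_length: int = DEFAULT_REGION,
) -> WindowCounts:
    """Window counts straight from a hit matrix (fast path for large scans)."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if region_length % window_size != 0:
        raise ValueError("window_size must divide region_length")
    n_windows = region_length // window_size
    counts = np.zeros(n_windows, dtype=np.int64)
    n_cols = min(hits.shape[1], region_length)
    if n_cols > 0:
        col_hits = hits[:, :n_cols].sum(axis=0, dtype=np.int64)
        windows = np.arange(n_cols) // window_size
        np.add.at(counts, windows, col_hits)
    eligible = _eligible_per_window(lengths, window_size, region_length)
    return WindowCounts(
        window_size=window_size,
        region_length=region_length,
        counts=counts,
        eligible_positions=eligible,
        n_genes=hits.shape[0],
    )


def call_targets(
    dataset: SpeciesDataset,
    profile: MotifProfile,
    utr_cutoff: int = DEFAULT_UTR_CUTOFF,
) -> TargetSet:
    """Call Puf3p targets: genes with a full match inside the first ``utr_cutoff`` bp.

    The whole 8-mer must end at or before the cutoff, i.e. 0-based start
    ``<= utr_cutoff - 8`` — an element half outside the UTR is not a site.
    """
    genes = dataset.genes
    codes, lengths = encode_sequences([dataset.downstream[g] for g in genes])
    hits = hit_matrix(codes, lengths, profile)
    max_start = utr_cutoff - MOTIF_LENGTH
    targets: set[str] = set()
    if hits.shape[1] > 0 and max_start >= 0:
        n_cols = min(max_start + 1, hits.shape[1])
        has = hits[:, :n_cols].any(axis=1)
        targets = {genes[i] for i in np.flatnonzero(has)}
    return TargetSet(species_id=dataset.species_id, targets=targets, utr_cutoff=utr_cutoff)
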