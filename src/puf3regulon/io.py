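"""Readers, writers and validated in-memory containers.

Every pipeline stage consumes the types defined here rather than raw files:
per-species FASTA of gene-anchored 3' downstream sequences and CDS, and TSV
tables for ortholog maps, localization annotations, function sets, expression
matrices and deletion-fitness measurements.  All tables are tab-separated with
a mandatory header; nothing is parsed positionally.

Downstream sequences are supplied pre-extracted: each record starts at the
first base after the stop codon, on the mRNA sense strand, and runs up to
1,000 bp (shorter when a gene sits near a contig end).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

#: IUPAC ambiguity codes other than N that ``ambiguous="map"`` collapses to N.
_AMBIGUITY = frozenset("RYSWKMBDHVU")

ORTHOLOG_COLUMNS = ("species_gene", "reference_gene")
LOCALIZATION_COLUMNS = ("gene", "compartment")
FUNCTION_SET_COLUMNS = ("set_name", "gene")
FITNESS_COLUMNS = ("gene", "condition", "relative_growth")


class FormatError(ValueError):
    """Raised when an input file violates its declared format contract."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class SpeciesDataset:
    """All per-species sequence data.

    Parameters
    ----------
    species_id:
        Unique species identifier (also used as a file-name stem).
    downstream:
        gene id -> 3' downstream sequence (ACGTN, length 1..1000).
    cds:
        gene id -> coding sequence (length >= 3 and divisible by 3).
    label:
        Free-form clade tag, e.g. ``"saccharomycotina_post_wgd"``.
    """

    species_id: str
    downstream: dict[str, str] = field(default_factory=dict)
    cds: dict[str, str] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        for gene, seq in self.downstream.items():
            if not seq:
                raise FormatError(f"{self.species_id}: empty downstream sequence for {gene}")
            if len(seq) > 1000:
                raise FormatError(
                    f"{self.species_id}: downstream of {gene} is {len(seq)} bp (> 1000)"
                )
            _check_alphabet(seq, gene)
        for gene, seq in self.cds.items():
            if len(seq) < 3 or len(seq) % 3 != 0:
                raise FormatError(
                    f"{self.species_id}: CDS of {gene} has length {len(seq)}, "
                    "expected >= 3 and divisible by 3"
                )
            _check_alphabet(seq, gene)

    @property
    def genes(self) -> list[str]:
        """Gene ids with a downstream region, in sorted order."""
        return sorted(self.downstream)


@dataclass
class OrthologMap:
    """Pairs linking species genes to reference-species genes (may be m:n)."""

    species_id: str
    reference_id: str
    pairs: set[tuple[str, str]] = field(default_factory=set)

    def by_species_gene(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for sp_gene, ref_gene in self.pairs:
            out.setdefault(sp_gene, set()).add(ref_gene)
        return out

    def by_reference_gene(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for sp_gene, ref_gene in self.pairs:
            out.setdefault(ref_gene, set()).add(sp_gene)
        return out


@dataclass
class AnnotationTable:
    """Reference-species annotations transferred through orthology.

    ``localization`` maps reference gene -> compartment label;
    ``function_sets`` maps set name -> reference gene set (e.g. the
    mitochondrial-translation gene list used for conservation profiling).
    """

    localization: dict[str, str] = field(default_factory=dict)
    function_sets: dict[str, set[str]] = field(default_factory=dict)
    compartments: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.compartments:
            self.compartments = tuple(sorted(set(self.localization.values())))
        vocab = set(self.compartments)
        for gene, comp in self.localization.items():
            if comp not in vocab:
                raise FormatError(f"compartment {comp!r} of {gene} not in vocabulary {sorted(vocab)}")
        for name, genes in self.function_sets.items():
            if not genes:
                raise FormatError(f"function set {name!r} is empty")


def _check_alphabet(seq: str, gene: str) -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        raise FormatError(f"invalid characters {sorted(bad)} in sequence of {gene}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, ambiguous: str = "strict") -> dict[str, str]:
    """Read a nucleotide FASTA into ``{gene_id: sequence}``.

    Sequences are uppercased; wrapped and unwrapped records are equivalent.
    ``ambiguous`` controls characters outside ACGTN: ``"strict"`` rejects
    them, ``"map"`` converts IUPAC ambiguity codes to N.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate id {rec.id}")
        seq = str(rec.seq).upper()
        if ambiguous == "map":
            seq = "".join("N" if c in _AMBIGUITY else c for c in seq)
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id} contains non-ACGTN characters {sorted(bad)} "
                "(use ambiguous='map' to collapse ambiguity codes to N)"
            )
        records[rec.id] = seq
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    """Write ``{gene_id: sequence}`` as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for gene in records:
            fh.write(f">{gene}\n")
            seq = records[gene]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_table(path: str | Path, columns: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a header-ed TSV, checking that ``columns`` are all present."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str} if columns else None)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise FormatError(
                f"{path}: missing columns {missing}; expected {list(columns)}, "
                f"found {list(df.columns)}"
            )
    return df


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV.

    P-value columns (names starting with ``p_`` or equal to ``p``) are
    rendered in scientific notation; all other floats keep full repr
    precision so that a round-trip read reproduces the table.
    """
    df = results.copy()
    for col in df.columns:
        if (col == "p" or str(col).startswith("p_")) and df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda x: f"{x:.12e}" if pd.notna(x) else "")
    df.to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | Path, species_id: str, reference_id: str = "reference") -> OrthologMap:
    df = read_table(path, ORTHOLOG_COLUMNS)
    pairs = set(zip(df["species_gene"].astype(str), df["reference_gene"].astype(str)))
    return OrthologMap(species_id=species_id, reference_id=reference_id, pairs=pairs)


def write_ortholog_map(orthologs: OrthologMap, path: str | Path) -> None:
    rows = sorted(orthologs.pairs)
    pd.DataFrame(rows, columns=list(ORTHOLOG_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_annotations(localization_path: str | Path, function_sets_path: str | Path | None = None) -> AnnotationTable:
    loc_df = read_table(localization_path, LOCALIZATION_COLUMNS)
    localization = dict(zip(loc_df["gene"].astype(str), loc_df["compartment"].astype(str)))
    function_sets: dict[str, set[str]] = {}
    if function_sets_path is not None:
        fs_df = read_table(function_sets_path, FUNCTION_SET_COLUMNS)
        for name, group in fs_df.groupby("set_name"):
            function_sets[str(name)] = set(group["gene"].astype(str))
    return AnnotationTable(localization=localization, function_sets=function_sets)


def write_annotations(annotations: AnnotationTable, localization_path: str | Path,
                      function_sets_path: str | Path | None = None) -> None:
    rows = sorted(annotations.localization.items())
    pd.DataFrame(rows, columns=list(LOCALIZATION_COLUMNS)).to_csv(localization_path, sep="\t", index=False)
    if function_sets_path is not None:
        fs_rows = [
            (name, gene)
            for name in sorted(annotations.function_sets)
            for gene in sorted(annotations.function_sets[name])
        ]
        pd.DataFrame(fs_rows, columns=list(FUNCTION_SET_COLUMNS)).to_csv(function_sets_path, sep="\t", index=False)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x conditions matrix of log2 ratios (first column ``gene``)."""
    df = read_table(path, ("gene",))
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup}")
    df = df.set_index("gene")
    if df.shape[1] < 1:
        raise FormatError(f"{path}: expression matrix needs at least one condition column")
    return df.astype(float)


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_fitness(path: str | Path) -> pd.DataFrame:
    df = read_table(path, FITNESS_COLUMNS)
    df["relative_growth"] = df["relative_growth"].astype(float)
    return df


def round_trip_equal(a: pd.DataFrame, b: pd.DataFrame, rel: float = 1e-9) -> bool:
    """True when two result tables agree field-for-field within printed precision."""
    if list(a.columns) != list(b.columns) or a.shape != b.shape:
        return False
    for col in a.columns:
        for x, y in zip(a[col], b[col]):
            if isinstance(x, float) or isinstance(y, float):
                x, y = float(x), float(y)
                if math.isnan(x) and math.isnan(y):
                    continue
                if not math.isclose(x, y, rel_tol=rel, abs_tol=1e-300):
                    return False
            elif str(x) != str(y):
                return False
    return True
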