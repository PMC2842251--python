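"""Readers and writers for the external file formats.

All sequences are normalised to an uppercase RNA alphabet (T mapped to U) on
the way in.  Coordinates are 0-based and half-open everywhere in memory;
1-based positions appear only in written reports.

Alignment input uses a small two-record-per-gene aligned-FASTA dialect::

    >geneX|human
    ACG-U...
    >geneX|mouse
    ACGAU...

The two gapped sequences of a gene must have equal length.  This is the
smallest dialect that preserves aligned columns, the only information the
downstream conservation call uses; ``read_alignment_pairs`` accepts a
``dialect`` hook for future converters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlphabetError",
    "StructuralError",
    "PairingError",
    "ParseError",
    "SchemaError",
    "UtrAlignmentPair",
    "MiRnaRecord",
    "ExpressionRecord",
    "read_alignment_pairs",
    "read_mirna_fasta",
    "read_expression_table",
    "write_hits_table",
    "read_hits_table",
    "HITS_COLUMNS",
]


class AlphabetError(ValueError):
    """A sequence contains characters outside the expected alphabet."""


class StructuralError(ValueError):
    """A record violates a structural invariant (e.g. unequal aligned lengths)."""


class PairingError(ValueError):
    """Alignment records do not come in complete human/mouse pairs."""


class ParseError(ValueError):
    """A header or field cannot be parsed."""


class SchemaError(ValueError):
    """A table is missing a required column."""


_RNA = frozenset("ACGU")
_RNA_GAP = frozenset("ACGU-")


def _normalise(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _check_alphabet(seq: str, allowed: frozenset, context: str) -> None:
    bad = set(seq) - allowed
    if bad:
        raise AlphabetError(f"{context}: non-IUPAC RNA character(s) {sorted(bad)!r}")


@dataclass
class UtrAlignmentPair:
    """One gene's aligned human and mouse 5'-UTR sequences (gapped, RNA)."""

    gene_id: str
    human_aligned: str
    mouse_aligned: str
    source_line: int = 0

    def __post_init__(self) -> None:
        if len(self.human_aligned) != len(self.mouse_aligned):
            raise StructuralError(
                f"gene {self.gene_id!r} (line {self.source_line}): aligned lengths "
                f"differ ({len(self.human_aligned)} vs {len(self.mouse_aligned)})"
            )
        for label, seq in (("human", self.human_aligned), ("mouse", self.mouse_aligned)):
            _check_alphabet(seq, _RNA_GAP, f"gene {self.gene_id!r} ({label})")
            if not seq.replace("-", ""):
                raise StructuralError(
                    f"gene {self.gene_id!r} ({label}): empty sequence after removing gaps"
                )

    @property
    def human_ungapped(self) -> str:
        return self.human_aligned.replace("-", "")

    @property
    def mouse_ungapped(self) -> str:
        return self.mouse_aligned.replace("-", "")


_MIRNA_NAME = re.compile(r"^([A-Za-z]{3})-(\S+)$")


@dataclass
class MiRnaRecord:
    """A mature miRNA with a miRBase-style name (e.g. ``hsa-let-7d``)."""

    name: str
    sequence: str
    species_prefix: str = field(init=False)
    base_name: str = field(init=False)

    def __post_init__(self) -> None:
        m = _MIRNA_NAME.match(self.name)
        if m is None:
            raise ParseError(
                f"miRNA name {self.name!r} lacks a three-letter species prefix"
            )
        self.species_prefix, self.base_name = m.group(1), m.group(2)
        self.sequence = _normalise(self.sequence)
        if not self.sequence:
            raise AlphabetError(f"miRNA {self.name!r}: empty sequence")
        _check_alphabet(self.sequence, _RNA, f"miRNA {self.name!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ExpressionRecord:
    """Presence/absence call for one miRNA in one cell line."""

    mirna_name: str
    cell_line: str
    expressed: bool
    source_tag: str = ""


def read_alignment_pairs(path, dialect: str = "two_record_fasta") -> list[UtrAlignmentPair]:
    """Read per-gene human/mouse aligned 5'-UTR pairs.

    Raises :class:`PairingError` on an odd record count or mismatched gene ids,
    :class:`StructuralError` on unequal aligned lengths and
    :class:`AlphabetError` on non-IUPAC characters.
    """
    if dialect != "two_record_fasta":
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2:
        raise PairingError(f"{path}: odd number of records ({len(records)})")
    pairs: list[UtrAlignmentPair] = []
    for idx in range(0, len(records), 2):
        first, second = records[idx], records[idx + 1]
        ids = {}
        for rec in (first, second):
            if "|" not in rec.id:
                raise ParseError(f"{path}: header {rec.id!r} is not 'gene|role'")
            gene, role = rec.id.split("|", 1)
            ids[role.lower()] = (gene, _normalise(str(rec.seq)))
        if set(ids) != {"human", "mouse"}:
            raise PairingError(
                f"{path}: records {first.id!r}/{second.id!r} are not a human/mouse pair"
            )
        if ids["human"][0] != ids["mouse"][0]:
            raise PairingError(
                f"{path}: gene ids differ within a pair "
                f"({ids['human'][0]!r} vs {ids['mouse'][0]!r})"
            )
        pairs.append(
            UtrAlignmentPair(
                gene_id=ids["human"][0],
                human_aligned=ids["human"][1],
                mouse_aligned=ids["mouse"][1],
                source_line=2 * idx + 1,
            )
        )
    return pairs


def write_alignment_pairs(pairs: Iterable[UtrAlignmentPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f">{p.gene_id}|human\n{p.human_aligned}\n")
            fh.write(f">{p.gene_id}|mouse\n{p.mouse_aligned}\n")


def read_mirna_fasta(path) -> list[MiRnaRecord]:
    """Read mature miRNA sequences from a miRBase-style FASTA file."""
    out: list[MiRnaRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.description.split()[0]
        if name in seen:
            raise ParseError(f"{path}: duplicate miRNA name {name!r}")
        seen.add(name)
        out.append(MiRnaRecord(name=name, sequence=str(rec.seq)))
    return out


def write_mirna_fasta(records: Iterable[MiRnaRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.name}\n{r.sequence}\n")


_TRUTHY = {"yes", "y", "1", "true"}
_FALSY = {"no", "n", "0", "false"}
_EXPR_COLUMNS = ["mirna", "cell_line", "expressed", "source"]


def read_expression_table(path) -> list[ExpressionRecord]:
    """Read a TSV of miRNA expression calls (columns mirna, cell_line, expressed, source)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _EXPR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    out: list[ExpressionRecord] = []
    seen: set[tuple] = set()
    for row in df.itertuples(index=False):
        token = str(row.expressed).strip().lower()
        if token in _TRUTHY:
            expressed = True
        elif token in _FALSY:
            expressed = False
        else:
            raise ValueError(f"{path}: invalid expressed token {row.expressed!r}")
        key = (row.mirna, row.cell_line, row.source)
        if key in seen:
            raise ValueError(f"{path}: duplicate record {key!r}")
        seen.add(key)
        out.append(
            ExpressionRecord(
                mirna_name=row.mirna,
                cell_line=row.cell_line,
                expressed=expressed,
                source_tag=row.source,
            )
        )
    return out


HITS_COLUMNS = [
    "gene",
    "motif",
    "motif_start",
    "conserved_motif",
    "mirna",
    "end",
    "stretch_len",
    "gu_count",
    "dG37",
]

_END_ORDER = {"5p": 0, "3p": 1}


def write_hits_table(hits: Sequence, path) -> None:
    """Write duplex hits as a TSV with a stable column and row order.

    Rows are sorted by (gene, motif_start, mirna, end) with the 3' end after
    the 5' end; energies are printed to 0.01 kcal/mol.
    """
    rows = [
        {
            "gene": h.motif.gene_id,
            "motif": h.motif.sequence,
            "motif_start": h.motif.aug_start_ungapped,
            "conserved_motif": h.motif.conserved,
            "mirna": h.mirna_name,
            "end": h.end,
            "stretch_len": h.stretch_len,
            "gu_count": h.gu_count,
            "dG37": round(h.dg37, 2),
        }
        for h in hits
    ]
    df = pd.DataFrame(rows, columns=HITS_COLUMNS)
    if len(df):
        df = df.sort_values(
            by=["gene", "motif_start", "mirna", "end"],
            key=lambda col: col.map(_END_ORDER) if col.name == "end" else col,
            kind="mergesort",
        )
    df.to_csv(path, sep="\t", index=False)


def read_hits_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HITS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df
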