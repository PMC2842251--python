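"""miRNA catalog operations: conservation classes, half splitting, shuffling.

A focal-species miRNA is *conserved* when its base name (the name with the
species prefix stripped) occurs under a different species prefix anywhere in
the multi-species catalog, irrespective of nucleotide-level identity.  Name
matching is exact up to case; arm variants such as ``miR-219-1-3p`` vs
``miR-219-2-3p`` are distinct.

Mature sequences are split into a 5' half (carrying the seed, positions 2–7)
and a 3' half.  For odd lengths the 3' half receives the extra nucleotide,
keeping the non-seed arm — the arm whose interactions this scan emphasises —
maximal: ``five = seq[:L//2]``, ``three = seq[L//2:]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import MiRnaRecord

__all__ = [
    "FIVE_P",
    "THREE_P",
    "MiRnaHalf",
    "CatalogPartition",
    "classify_conservation",
    "split_halves",
    "shuffle_mirna",
]

FIVE_P = "5p"
THREE_P = "3p"


@dataclass(frozen=True)
class MiRnaHalf:
    """One half of a mature miRNA (``end`` is ``"5p"`` or ``"3p"``)."""

    parent_name: str
    end: str
    sequence: str


@dataclass
class CatalogPartition:
    """Focal-species miRNAs partitioned into conserved / non-conserved."""

    conserved: list[MiRnaRecord]
    non_conserved: list[MiRnaRecord]

    @property
    def all_records(self) -> list[MiRnaRecord]:
        return self.conserved + self.non_conserved


def classify_conservation(
    focal: list[MiRnaRecord], all_species: list[MiRnaRecord]
) -> CatalogPartition:
    """Partition ``focal`` by cross-species presence of the base name."""
    prefixes = {r.species_prefix.lower() for r in focal}
    if len(prefixes) > 1:
        raise ValueError(f"focal records span multiple species: {sorted(prefixes)}")
    if not all_species:
        warnings.warn("empty multi-species catalog: all miRNAs classified non-conserved")
    other_names = {
        r.base_name.lower()
        for r in all_species
        if r.species_prefix.lower() not in prefixes
    }
    conserved, non_conserved = [], []
    for rec in focal:
        (conserved if rec.base_name.lower() in other_names else non_conserved).append(rec)
    return CatalogPartition(conserved=conserved, non_conserved=non_conserved)


def split_halves(record: MiRnaRecord) -> tuple[MiRnaHalf, MiRnaHalf]:
    """Split a mature sequence into its 5' and 3' halves."""
    seq = record.sequence
    if len(seq) < 2:
        raise ValueError(f"miRNA {record.name!r} too short to split ({len(seq)} nt)")
    mid = len(seq) // 2
    return (
        MiRnaHalf(parent_name=record.name, end=FIVE_P, sequence=seq[:mid]),
        MiRnaHalf(parent_name=record.name, end=THREE_P, sequence=seq[mid:]),
    )


def shuffle_mirna(record: MiRnaRecord, rng: np.random.Generator) -> MiRnaRecord:
    """Return a composition-preserving shuffle of the full mature sequence.

    The permutation is uniform over letter orderings.  Halves must be
    re-derived from the shuffled sequence afterwards; shuffling halves
    separately would preserve per-half composition, which is a different
    (and not the documented) null.
    """
    letters = np.array(list(record.sequence))
    shuffled = "".join(letters[rng.permutation(len(letters))])
    return MiRnaRecord(name=f"{record.name}|shuf", sequence=shuffled)
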