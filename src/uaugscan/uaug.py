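"""uAUG motif extraction and human/mouse conservation classification.

An upstream AUG (uAUG) is any AUG triplet in a 5'-UTR.  For each occurrence
we cut an 11-nt window spanning four nucleotides upstream of the A through
four nucleotides downstream of the G (positions −4..+7 with the A as +1).
Near the ends of the UTR the window is clipped; clipped windows shorter than
7 nt are discarded, and the AUG itself always survives clipping.

A motif is *conserved* when every alignment column covering it carries an
identical mouse nucleotide and the mouse segment has no insertion inside the
span — the strictest reading of 100% identity with the mouse homolog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import UtrAlignmentPair

__all__ = [
    "UAugMotif",
    "MotifSummary",
    "find_uaugs",
    "extract_motif",
    "classify_motif_conservation",
    "extract_all",
    "FLANK",
    "MIN_MOTIF_LEN",
    "FULL_MOTIF_LEN",
]

FLANK = 4
MIN_MOTIF_LEN = 7
FULL_MOTIF_LEN = 11


@dataclass
class UAugMotif:
    """A 7–11 nt uAUG-centered subsequence of a human 5'-UTR.

    ``aug_start_ungapped`` indexes the A of the AUG in the gap-stripped UTR
    (0-based).  ``mutant`` marks experimentally mutated windows that need not
    contain an AUG; for those ``aug_offset`` records where the AUG was.
    """

    gene_id: str
    aug_start_ungapped: int
    sequence: str
    aug_offset: int
    conserved: bool = False
    mutant: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not MIN_MOTIF_LEN <= n <= FULL_MOTIF_LEN:
            raise ValueError(f"motif length {n} outside [7, 11]: {self.sequence!r}")
        if not (self.aug_offset <= FLANK and n - self.aug_offset >= 3):
            raise ValueError(
                f"AUG offset {self.aug_offset} leaves no room for a triplet "
                f"in {self.sequence!r}"
            )
        if not self.mutant and self.sequence[self.aug_offset : self.aug_offset + 3] != "AUG":
            raise ValueError(
                f"no AUG at offset {self.aug_offset} of {self.sequence!r}"
            )


@dataclass
class MotifSummary:
    """Per-dataset summary: uAUGs per UTR and conserved fraction by motif length."""

    uaug_counts_per_utr: dict[int, int] = field(default_factory=dict)
    conserved_fraction_by_n: dict[int, float] = field(default_factory=dict)


def find_uaugs(utr_ungapped: str) -> list[int]:
    """Return every (possibly overlapping) AUG start index, ascending."""
    out = []
    start = utr_ungapped.find("AUG")
    while start != -1:
        out.append(start)
        start = utr_ungapped.find("AUG", start + 1)
    return out


def extract_motif(utr_ungapped: str, aug_start: int, gene_id: str = "") -> UAugMotif | None:
    """Cut the −4..+7 window around an AUG; ``None`` if the clipped window is < 7 nt."""
    if utr_ungapped[aug_start : aug_start + 3] != "AUG":
        raise ValueError(f"no AUG at position {aug_start}")
    lo = max(aug_start - FLANK, 0)
    hi = min(aug_start + 3 + FLANK, len(utr_ungapped))
    if hi - lo < MIN_MOTIF_LEN:
        return None
    return UAugMotif(
        gene_id=gene_id,
        aug_start_ungapped=aug_start,
        sequence=utr_ungapped[lo:hi],
        aug_offset=aug_start - lo,
    )


def _ungapped_to_columns(aligned: str) -> list[int]:
    """Map each ungapped position of ``aligned`` to its alignment column."""
    return [col for col, ch in enumerate(aligned) if ch != "-"]


def classify_motif_conservation(pair: UtrAlignmentPair, motif: UAugMotif) -> bool:
    """True iff the motif's alignment span is 100% identical in mouse.

    Any substitution, mouse gap, or mouse insertion (a human-gap column)
    inside the span makes the motif non-conserved.
    """
    cols = _ungapped_to_columns(pair.human_aligned)
    start = motif.aug_start_ungapped - motif.aug_offset
    end = start + len(motif.sequence)
    if end > len(cols):
        raise ValueError(
            f"motif at {motif.aug_start_ungapped} not mappable to alignment "
            f"of gene {pair.gene_id!r}"
        )
    span = range(cols[start], cols[end - 1] + 1)
    for c in span:
        if pair.human_aligned[c] == "-":  # mouse insertion inside the span
            return False
        if pair.mouse_aligned[c] != pair.human_aligned[c]:
            return False
    return True


def extract_all(pairs: list[UtrAlignmentPair]) -> tuple[list[UAugMotif], MotifSummary]:
    """Extract and classify every uAUG motif; compute the dataset summary.

    Duplicate motif sequences are retained as separate occurrences.  The
    per-UTR histogram counts extracted motifs (windows ≥ 7 nt) and includes
    UTRs with zero motifs, so its counts sum to ``len(pairs)``.
    """
    motifs: list[UAugMotif] = []
    counts: dict[int, int] = {}
    by_n_total: dict[int, int] = {}
    by_n_cons: dict[int, int] = {}
    for pair in pairs:
        utr = pair.human_ungapped
        n_here = 0
        for aug in find_uaugs(utr):
            motif = extract_motif(utr, aug, gene_id=pair.gene_id)
            if motif is None:
                continue
            motif.conserved = classify_motif_conservation(pair, motif)
            motifs.append(motif)
            n_here += 1
            n = len(motif.sequence)
            by_n_total[n] = by_n_total.get(n, 0) + 1
            if motif.conserved:
                by_n_cons[n] = by_n_cons.get(n, 0) + 1
        counts[n_here] = counts.get(n_here, 0) + 1
    fractions = {
        n: by_n_cons.get(n, 0) / total for n, total in sorted(by_n_total.items())
    }
    return motifs, MotifSummary(uaug_counts_per_utr=counts, conserved_fraction_by_n=fractions)
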