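"""Gene-level meta-analysis: scan a gene's uAUGs (wild-type and mutant
windows) against conserved miRNAs, attach repression-strength annotations
and cell-line expression evidence, and build per-gene reports.

Repression folds (1x–6x) quantify how strongly a uAUG suppresses a
downstream reporter relative to a control or mutated construct; they are
experimental annotations transcribed from the literature and consumed as
data, never computed here.  Mutant windows run through exactly the same
search path as wild-type ones — nothing in the scan special-cases the
mutant flag — so any change in predicted miRNAs is attributable to sequence
complementarity alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .catalog import CatalogPartition
from .energy import EnergyParameters, default_energy
from .io import ExpressionRecord
from .search import DuplexHit, SearchParams, scan
from .uaug import FULL_MOTIF_LEN, MIN_MOTIF_LEN, UAugMotif, extract_motif, find_uaugs

__all__ = [
    "META_PARAMS",
    "RepressionAnnotation",
    "ReportRow",
    "GeneReport",
    "scan_gene",
    "windows_to_motifs",
    "join_expression",
    "summarize_fold_association",
]

#: Gene-level wobble policy: one G·U wobble allowed against the 3' end,
#: none against the 5' end.
META_PARAMS = SearchParams(max_gu_3p=1, max_gu_5p=0)


@dataclass(frozen=True)
class RepressionAnnotation:
    """Discrete 1x–6x repressive-strength call for one uAUG motif."""

    gene_id: str
    motif_label: str
    fold: int
    cell_line: str = ""
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.fold not in (1, 2, 3, 4, 5, 6):
            raise ValueError(f"fold must be in 1..6, got {self.fold}")


@dataclass(frozen=True)
class ReportRow:
    motif_label: str
    motif_sequence: str
    fold: int | None
    mirna_name: str | None
    end: str | None
    expressed: bool | None  # None = unknown (no record for this miRNA/cell line)
    source_tag: str = ""


@dataclass
class GeneReport:
    gene_id: str
    cell_line: str
    rows: list[ReportRow] = field(default_factory=list)


def windows_to_motifs(
    gene_id: str, windows: Sequence[tuple[str, str, bool]]
) -> list[UAugMotif]:
    """Build motifs from printed (label, 7–11-mer, is_mutant) windows.

    Mutant windows need not contain an AUG; their AUG offset is recorded as
    the canonical window offset (4 for a full 11-mer).
    """
    motifs = []
    for idx, (label, seq, mutant) in enumerate(windows):
        seq = seq.upper().replace("T", "U")
        if not MIN_MOTIF_LEN <= len(seq) <= FULL_MOTIF_LEN:
            raise ValueError(f"window {label!r} is {len(seq)} nt, need 7-11")
        if mutant:
            offset = min(4, len(seq) - 3)
        else:
            offset = seq.find("AUG")
            if offset == -1 or offset > 4:
                raise ValueError(f"window {label!r} has no uAUG within offset 0-4")
        motifs.append(
            UAugMotif(
                gene_id=gene_id,
                aug_start_ungapped=idx,  # ordinal position; windows are printed inputs
                sequence=seq,
                aug_offset=offset,
                mutant=mutant,
                label=label,
            )
        )
    return motifs


def scan_gene(
    gene_id: str,
    catalog: CatalogPartition,
    utr: str | None = None,
    windows: Sequence[tuple[str, str, bool]] = (),
    params: SearchParams = META_PARAMS,
    energy: EnergyParameters | None = None,
) -> tuple[list[UAugMotif], list[DuplexHit]]:
    """Scan a gene's uAUG motifs against conserved miRNAs only.

    Motifs come from the gene's 5'-UTR (``utr``), from printed windows
    (``windows`` of (label, sequence, is_mutant)), or both.
    """
    energy = energy or default_energy()
    motifs: list[UAugMotif] = []
    if utr is not None:
        utr = utr.upper().replace("T", "U")
        for aug in find_uaugs(utr):
            motif = extract_motif(utr, aug, gene_id=gene_id)
            if motif is not None:
                motif.label = f"uAUG@{aug}"
                motifs.append(motif)
    motifs.extend(windows_to_motifs(gene_id, windows))
    conserved_only = CatalogPartition(conserved=catalog.conserved, non_conserved=[])
    hits = scan(motifs, conserved_only, params, energy)
    return motifs, hits


def join_expression(
    gene_id: str,
    motifs: Sequence[UAugMotif],
    hits: Sequence[DuplexHit],
    expression: Sequence[ExpressionRecord],
    cell_line: str,
    annotations: Sequence[RepressionAnnotation] = (),
) -> GeneReport:
    """Annotate each hit with expression evidence for one cell line.

    Motifs without any hit contribute a row with ``mirna_name=None`` so the
    report mirrors printed per-gene tables, where such uAUGs read "None".
    """
    folds = {a.motif_label: a.fold for a in annotations if a.gene_id == gene_id}
    calls: dict[str, tuple[bool, str]] = {}
    for rec in expression:
        if rec.cell_line == cell_line:
            calls[rec.mirna_name] = (rec.expressed, rec.source_tag)
    rows: list[ReportRow] = []
    hit_motif_ids = {id(h.motif) for h in hits}
    for motif in motifs:
        if id(motif) not in hit_motif_ids:
            rows.append(
                ReportRow(
                    motif_label=motif.label,
                    motif_sequence=motif.sequence,
                    fold=folds.get(motif.label),
                    mirna_name=None,
                    end=None,
                    expressed=None,
                )
            )
    for h in hits:
        expressed, source = calls.get(h.mirna_name, (None, ""))
        rows.append(
            ReportRow(
                motif_label=h.motif.label,
                motif_sequence=h.motif.sequence,
                fold=folds.get(h.motif.label),
                mirna_name=h.mirna_name,
                end=h.end,
                expressed=expressed,
                source_tag=source,
            )
        )
    return GeneReport(gene_id=gene_id, cell_line=cell_line, rows=rows)


def summarize_fold_association(report: GeneReport) -> pd.DataFrame:
    """Per fold value: number of motifs, and motifs with >= 1 expressed-miRNA hit."""
    per_motif: dict[str, tuple[int, bool]] = {}
    for row in report.rows:
        if row.fold is None:
            continue
        prev = per_motif.get(row.motif_label, (row.fold, False))
        has_expr = prev[1] or (row.mirna_name is not None and row.expressed is True)
        per_motif[row.motif_label] = (row.fold, has_expr)
    agg: dict[int, list[int]] = {}
    for fold, has_expr in per_motif.values():
        n, k = agg.get(fold, [0, 0])
        agg[fold] = [n + 1, k + int(has_expr)]
    rows = [
        {"fold": fold, "n_motifs": n, "n_motifs_with_expressed_mirna_hit": k}
        for fold, (n, k) in sorted(agg.items())
    ]
    return pd.DataFrame(rows, columns=["fold", "n_motifs", "n_motifs_with_expressed_mirna_hit"])
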