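"""Two-step complementarity search between uAUG motifs and miRNA halves.

Step one finds the longest run of consecutive paired positions between the
motif (5'→3') and a miRNA half (antiparallel), where every position is a
Watson-Crick pair or a G·U wobble and the number of wobbles is bounded.
Step two scores that run with the nearest-neighbor duplex energy and keeps
the pair only if the run is at least ``min_stretch`` long *and* the energy
is at or below ``dg_cutoff``.  The two criteria are conjunctive.

Ties between equal-length runs are broken by fewer wobbles, then smaller
motif start, then smaller half start (5'→3' coordinates), making all
outputs deterministic.

``scan`` evaluates every (motif occurrence, miRNA, end) triple.  A
numba-compiled batch kernel prefilters pairs by maximum run length; exact
spans, tie-breaks and energies are then recomputed in Python for the few
candidates, so the kernel can never change which hits are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .catalog import FIVE_P, THREE_P, CatalogPartition, MiRnaHalf, split_halves
from .energy import ALL_PAIRS, WOBBLE_PAIRS, EnergyParameters, default_energy, duplex_free_energy
from .uaug import UAugMotif

__all__ = [
    "SearchParams",
    "Stretch",
    "DuplexHit",
    "longest_complementary_stretch",
    "find_hit",
    "scan",
]


@dataclass(frozen=True)
class SearchParams:
    """Thresholds of the two-step screen.

    ``max_gu_5p``/``max_gu_3p`` bound the number of G·U wobbles allowed in a
    run against the 5' and 3' half respectively.  Genome-scale runs use the
    same bound for both ends (0 or 1); gene-level reports use 1 for the 3'
    end and 0 for the 5' end.
    """

    dg_cutoff: float = -14.0
    min_stretch: int = 7
    max_gu_5p: int = 0
    max_gu_3p: int = 0

    def __post_init__(self) -> None:
        if self.dg_cutoff >= 0:
            raise ValueError("dg_cutoff must be negative")
        if self.min_stretch < 1 or self.max_gu_5p < 0 or self.max_gu_3p < 0:
            raise ValueError("min_stretch must be >= 1 and wobble bounds >= 0")

    def max_gu(self, end: str) -> int:
        return self.max_gu_5p if end == FIVE_P else self.max_gu_3p


@dataclass(frozen=True)
class Stretch:
    """Best run of consecutive pairings; spans are 0-based half-open, 5'→3'."""

    length: int
    gu_count: int
    motif_span: tuple[int, int]
    half_span: tuple[int, int]


@dataclass(frozen=True)
class DuplexHit:
    """One motif × miRNA-half interaction passing both screening steps."""

    motif: UAugMotif
    mirna_name: str
    end: str
    stretch_len: int
    gu_count: int
    dg37: float
    motif_span: tuple[int, int]
    half_span: tuple[int, int]
    mirna_conserved: bool = False


def _pair_state(x: str, y: str) -> int:
    """0 = no pair, 1 = Watson-Crick, 2 = G·U wobble."""
    p = x + y
    if p in WOBBLE_PAIRS:
        return 2
    if p in ALL_PAIRS:
        return 1
    return 0


EMPTY_STRETCH = Stretch(0, 0, (0, 0), (0, 0))


def longest_complementary_stretch(
    motif_seq: str, half_seq: str, max_gu: int
) -> Stretch:
    """Best run of consecutive WC/G·U pairings between motif and half.

    The half is read antiparallel: motif position ``i`` pairs half position
    ``j`` with ``j`` decreasing as ``i`` increases.  Returns the zero-length
    stretch when no position can pair.
    """
    if not motif_seq or not half_seq:
        raise ValueError("sequences must be non-empty")
    m, h = len(motif_seq), len(half_seq)
    best = EMPTY_STRETCH
    # Diagonal d fixes i + j = d; walk i upward with a wobble-bounded window.
    for d in range(m + h - 1):
        i_lo = max(0, d - h + 1)
        i_hi = min(m - 1, d)
        start = i_lo
        wob: list[int] = []
        for i in range(i_lo, i_hi + 1):
            state = _pair_state(motif_seq[i], half_seq[d - i])
            if state == 0:
                start = i + 1
                wob.clear()
                continue
            if state == 2:
                wob.append(i)
                if len(wob) > max_gu:
                    start = wob.pop(0) + 1
            length = i - start + 1
            cand = (length, -len(wob), -start)
            inc = (best.length, -best.gu_count, -best.motif_span[0])
            if cand > inc or (
                cand == inc and (d - i) < best.half_span[0]
            ):
                best = Stretch(
                    length=length,
                    gu_count=len(wob),
                    motif_span=(start, i + 1),
                    half_span=(d - i, d - start + 1),
                )
    return best


def find_hit(
    motif: UAugMotif,
    half: MiRnaHalf,
    params: SearchParams,
    energy: EnergyParameters | None = None,
    mirna_conserved: bool = False,
) -> DuplexHit | None:
    """Apply both screening steps to one motif × half pair."""
    energy = energy or default_energy()
    stretch = longest_complementary_stretch(
        motif.sequence, half.sequence, params.max_gu(half.end)
    )
    if stretch.length < params.min_stretch:
        return None
    motif_sub = motif.sequence[stretch.motif_span[0] : stretch.motif_span[1]]
    half_sub = half.sequence[stretch.half_span[0] : stretch.half_span[1]]
    dg = duplex_free_energy(motif_sub, half_sub, energy)
    if dg > params.dg_cutoff:
        return None
    return DuplexHit(
        motif=motif,
        mirna_name=half.parent_name,
        end=half.end,
        stretch_len=stretch.length,
        gu_count=stretch.gu_count,
        dg37=dg,
        motif_span=stretch.motif_span,
        half_span=stretch.half_span,
        mirna_conserved=mirna_conserved,
    )


_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def encode_sequences(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Pack sequences into an int8 matrix (padded with -1) plus a length vector."""
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    width = int(lens.max()) if len(seqs) else 0
    mat = np.full((len(seqs), width), -1, dtype=np.int8)
    for r, s in enumerate(seqs):
        mat[r, : len(s)] = [_CODE[c] for c in s]
    return mat, lens


def _batch_max_stretch_python(m_codes, m_lens, h_codes, h_lens, max_gu):
    out = np.zeros((m_codes.shape[0], h_codes.shape[0]), dtype=np.int16)
    for a in range(m_codes.shape[0]):
        for b in range(h_codes.shape[0]):
            out[a, b] = _max_stretch_codes(
                m_codes[a], int(m_lens[a]), h_codes[b], int(h_lens[b]), max_gu
            )
    return out


def _max_stretch_codes(mc, ml, hc, hl, max_gu):
    best = 0
    for d in range(ml + hl - 1):
        i_lo = 0 if d - hl + 1 < 0 else d - hl + 1
        i_hi = min(ml - 1, d)
        start = i_lo
        run_wobs = []
        for i in range(i_lo, i_hi + 1):
            s = mc[i] + hc[d - i]
            if s == 3:
                state = 1
            elif s == 5:
                state = 2
            else:
                state = 0
            if state == 0:
                start = i + 1
                run_wobs = []
                continue
            if state == 2:
                run_wobs.append(i)
                if len(run_wobs) > max_gu:
                    start = run_wobs.pop(0) + 1
            if i - start + 1 > best:
                best = i - start + 1
    return best


try:  # pragma: no cover - exercised indirectly through scan()
    from numba import njit

    @njit(cache=False)
    def _batch_max_stretch_numba(m_codes, m_lens, h_codes, h_lens, max_gu):  # pragma: no cover
        n_m = m_codes.shape[0]
        n_h = h_codes.shape[0]
        out = np.zeros((n_m, n_h), dtype=np.int16)
        wob = np.empty(64, dtype=np.int64)
        for a in range(n_m):
            ml = m_lens[a]
            for b in range(n_h):
                hl = h_lens[b]
                best = 0
                for d in range(ml + hl - 1):
                    i_lo = d - hl + 1
                    if i_lo < 0:
                        i_lo = 0
                    i_hi = d
                    if i_hi > ml - 1:
                        i_hi = ml - 1
                    start = i_lo
                    w_head = 0
                    w_tail = 0
                    for i in range(i_lo, i_hi + 1):
                        s = m_codes[a, i] + h_codes[b, d - i]
                        if s == 3:
                            state = 1
                        elif s == 5:
                            state = 2
                        else:
                            state = 0
                        if state == 0:
                            start = i + 1
                            w_head = w_tail
                            continue
                        if state == 2:
                            wob[w_tail % 64] = i
                            w_tail += 1
                            if w_tail - w_head > max_gu:
                                start = wob[w_head % 64] + 1
                                w_head += 1
                        if i - start + 1 > best:
                            best = i - start + 1
                out[a, b] = best
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def batch_max_stretch(m_codes, m_lens, h_codes, h_lens, max_gu, use_numba=True):
    """Maximum stretch length for every (motif, half) pair of two encoded batches."""
    if use_numba and _HAVE_NUMBA:
        return _batch_max_stretch_numba(m_codes, m_lens, h_codes, h_lens, max_gu)
    return _batch_max_stretch_python(m_codes, m_lens, h_codes, h_lens, max_gu)


@dataclass
class _HalfBatch:
    halves: list[MiRnaHalf]
    conserved: list[bool]
    codes: np.ndarray
    lens: np.ndarray


def _half_batches(catalog: CatalogPartition) -> dict[str, _HalfBatch]:
    by_end: dict[str, tuple[list[MiRnaHalf], list[bool]]] = {FIVE_P: ([], []), THREE_P: ([], [])}
    for conserved, records in ((True, catalog.conserved), (False, catalog.non_conserved)):
        for rec in records:
            for half in split_halves(rec):
                by_end[half.end][0].append(half)
                by_end[half.end][1].append(conserved)
    out = {}
    for end, (halves, cons) in by_end.items():
        codes, lens = encode_sequences([h.sequence for h in halves])
        out[end] = _HalfBatch(halves=halves, conserved=cons, codes=codes, lens=lens)
    return out


def scan(
    motifs: Sequence[UAugMotif],
    catalog: CatalogPartition,
    params: SearchParams | None = None,
    energy: EnergyParameters | None = None,
    use_numba: bool = True,
) -> list[DuplexHit]:
    """All (motif occurrence, miRNA, end) hits, in deterministic order.

    Order is motif index, then miRNA name, with the 5' end before the 3'.
    """
    params = params or SearchParams()
    energy = energy or default_energy()
    if not motifs:
        return []
    m_codes, m_lens = encode_sequences([m.sequence for m in motifs])
    batches = _half_batches(catalog)
    hits_by_key: dict[tuple[int, str, int], DuplexHit] = {}
    for end_idx, end in enumerate((FIVE_P, THREE_P)):
        batch = batches[end]
        if not batch.halves:
            continue
        maxlen = batch_max_stretch(
            m_codes, m_lens, batch.codes, batch.lens, params.max_gu(end), use_numba
        )
        cand_m, cand_h = np.nonzero(maxlen >= params.min_stretch)
        for a, b in zip(cand_m.tolist(), cand_h.tolist()):
            hit = find_hit(
                motifs[a], batch.halves[b], params, energy,
                mirna_conserved=batch.conserved[b],
            )
            if hit is not None:
                hits_by_key[(a, hit.mirna_name, end_idx)] = hit
    return [hits_by_key[k] for k in sorted(hits_by_key)]
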