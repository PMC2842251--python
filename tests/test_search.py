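"""The two-step complementarity search: stretch finding, conjunctive
filtering, scanning, and equivalence with a brute-force oracle."""

from __future__ import annotations

import random

import pytest

from uaugscan.catalog import CatalogPartition, MiRnaHalf, split_halves
from uaugscan.energy import EnergyParameters
from uaugscan.io import MiRnaRecord
from uaugscan.search import (
    SearchParams,
    encode_sequences,
    batch_max_stretch,
    find_hit,
    longest_complementary_stretch,
    scan,
)
from uaugscan.uaug import UAugMotif

from conftest import brute_force_max_stretch, random_rna

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp(seq):
    return "".join(COMP[c] for c in reversed(seq))


def motif_of(seq, gene="g", conserved=False):
    off = seq.find("AUG")
    return UAugMotif(
        gene_id=gene, aug_start_ungapped=max(off, 0), sequence=seq,
        aug_offset=off if 0 <= off <= 4 else min(4, len(seq) - 3),
        conserved=conserved, mutant=off == -1 or off > 4,
    )


class TestLongestStretch:
    @pytest.mark.parametrize(
        "motif, expected_len",
        [("AACUAUG", 7), ("ACUAUGCAA", 9), ("CUAUGCAAC", 9)],
    )
    def test_let7d_three_prime_half_motifs(self, let7d, motif, expected_len):
        three = split_halves(let7d)[1]
        s = longest_complementary_stretch(motif, three.sequence, 0)
        assert s.length == expected_len
        assert s.gu_count == 0

    def test_a_cannot_pair_a(self):
        s = longest_complementary_stretch("AAAAAAA", "AAAAAAA", 1)
        assert s.length == 0

    def test_pure_wobble_run_bounded_by_allowance(self):
        s = longest_complementary_stretch("GGGGGGG", "UUUUUUU", 1)
        assert (s.length, s.gu_count) == (1, 1)
        assert longest_complementary_stretch("GGGGGGG", "UUUUUUU", 2).length == 2

    def test_klf9_uaug7_against_mir31(self, mir31):
        three = split_halves(mir31)[1]
        s = longest_complementary_stretch("GAGAAUGCCGG", three.sequence, 1)
        assert (s.length, s.gu_count) == (7, 1)
        assert longest_complementary_stretch("GAGAAUGCCGG", three.sequence, 0).length == 5

    def test_spans_index_the_paired_subsequences(self):
        half = "GUUGCAUAGUU"
        s = longest_complementary_stretch("CUAUGCAAC", half, 0)
        motif_sub = "CUAUGCAAC"[s.motif_span[0] : s.motif_span[1]]
        half_sub = half[s.half_span[0] : s.half_span[1]]
        assert motif_sub == revcomp(half_sub)

    def test_tie_break_prefers_fewer_wobbles(self):
        # two length-3 runs: GGG/UUU-ish wobble run vs a clean WC run
        s = longest_complementary_stretch("GGGAAA", "UUUCCC", 3)
        # AAA pairs UUU (WC, left part of half read antiparallel);
        # GGG pairs UUU only via wobbles
        assert s.gu_count == 0

    def test_oracle_equivalence_random(self):
        rng = random.Random(2)
        for _ in range(800):
            m = random_rna(rng, rng.randint(1, 12))
            h = random_rna(rng, rng.randint(1, 12))
            for max_gu in (0, 1, 2):
                got = longest_complementary_stretch(m, h, max_gu)
                assert got.length == brute_force_max_stretch(m, h, max_gu)
                if got.length:
                    sub_m = m[got.motif_span[0] : got.motif_span[1]]
                    sub_h = h[got.half_span[0] : got.half_span[1]]
                    wob = sum(
                        1
                        for a, b in zip(sub_m, reversed(sub_h))
                        if a + b in ("GU", "UG")
                    )
                    assert wob == got.gu_count <= max_gu

    def test_strand_symmetry(self):
        """Reverse-complementing both strands (swapping roles) preserves pure
        WC stretch lengths; wobble-tolerant runs are preserved under the
        reverse-and-swap symmetry (G·U maps to A·C under complementation, so
        revcomp symmetry only holds wobble-free)."""
        rng = random.Random(13)
        for _ in range(200):
            m = random_rna(rng, rng.randint(1, 12))
            h = random_rna(rng, rng.randint(1, 12))
            assert (
                longest_complementary_stretch(m, h, 0).length
                == longest_complementary_stretch(revcomp(h), revcomp(m), 0).length
            )
            assert (
                longest_complementary_stretch(m, h, 1).length
                == longest_complementary_stretch(h[::-1], m[::-1], 1).length
            )

    def test_extension_monotonicity(self):
        rng = random.Random(17)
        for _ in range(100):
            m = random_rna(rng, rng.randint(2, 9))
            h = random_rna(rng, rng.randint(2, 9))
            base = longest_complementary_stretch(m, h, 1).length
            ext = longest_complementary_stretch("G" + m + "G", "C" + h + "C", 1).length
            assert ext >= base

    def test_batch_kernel_agrees_with_scalar(self):
        rng = random.Random(23)
        motifs = [random_rna(rng, rng.randint(7, 11)) for _ in range(25)]
        halves = [random_rna(rng, rng.randint(8, 12)) for _ in range(25)]
        mc, ml = encode_sequences(motifs)
        hc, hl = encode_sequences(halves)
        for max_gu in (0, 1):
            for use_numba in (False, True):
                out = batch_max_stretch(mc, ml, hc, hl, max_gu, use_numba=use_numba)
                for a, m in enumerate(motifs):
                    for b, h in enumerate(halves):
                        assert out[a, b] == longest_complementary_stretch(m, h, max_gu).length


class TestFindHit:
    def test_two_criteria_are_conjunctive(self):
        """An AU-only perfect 7-mer passes the length filter but not the
        energy screen; the pair must be rejected."""
        motif = motif_of("AUAUAUA")
        half = MiRnaHalf("hsa-miR-x", "3p", revcomp("AUAUAUA"))
        params = SearchParams(max_gu_3p=1)
        assert find_hit(motif, half, params) is None
        relaxed = SearchParams(dg_cutoff=-1.0, max_gu_3p=1)
        assert find_hit(motif, half, relaxed) is not None

    def test_half_shorter_than_min_stretch_never_hits(self):
        motif = motif_of("GGGGAUGCCCC")
        half = MiRnaHalf("hsa-miR-x", "5p", "GGCAU")
        assert find_hit(motif, half, SearchParams()) is None

    def test_gc_rich_perfect_complement_hits(self):
        motif = motif_of("GCGCAUGGCGC")
        half = MiRnaHalf("hsa-miR-x", "3p", revcomp("GCGCAUGGCGC"))
        hit = find_hit(motif, half, SearchParams())
        assert hit is not None
        assert hit.stretch_len == 11
        assert hit.dg37 <= -14.0

    def test_klf9_mir31_fails_default_screen_but_not_relaxed(self, mir31):
        """The 7-bp, one-wobble uAUG7 x miR-31 stretch scores -12.9 kcal/mol,
        above the -14 screening threshold; with the threshold relaxed the
        hit appears and the AUG->AAG mutant still loses it."""
        three = split_halves(mir31)[1]
        wild = motif_of("GAGAAUGCCGG")
        mut = motif_of("GAGAAAGCCGG")
        default = SearchParams(max_gu_3p=1)
        assert find_hit(wild, three, default) is None
        relaxed = SearchParams(dg_cutoff=-12.0, max_gu_3p=1)
        hit = find_hit(wild, three, relaxed)
        assert hit is not None
        assert hit.dg37 == pytest.approx(-12.9, abs=1e-9)
        assert find_hit(mut, three, relaxed) is None


class TestScan:
    def _catalog(self, seqs_cons, seqs_noncons=()):
        cons = [MiRnaRecord(f"hsa-miR-c{i}", s) for i, s in enumerate(seqs_cons)]
        non = [MiRnaRecord(f"hsa-miR-n{i}", s) for i, s in enumerate(seqs_noncons)]
        return CatalogPartition(conserved=cons, non_conserved=non)

    def test_empty_motifs_give_empty_hits(self):
        assert scan([], self._catalog(["ACGUACGUACGUACGUACGUAC"])) == []

    def test_planted_reverse_complements_are_recovered(self):
        rng = random.Random(31)
        catalog = self._catalog(
            [random_rna(rng, 22) for _ in range(5)], [random_rna(rng, 22) for _ in range(3)]
        )
        motifs = []
        expected = set()
        for rec in catalog.conserved:
            three = split_halves(rec)[1]
            window = revcomp(three.sequence)
            motifs.append(
                UAugMotif(
                    gene_id=rec.name, aug_start_ungapped=4, sequence=window,
                    aug_offset=4, mutant=window[4:7] != "AUG",
                )
            )
            expected.add((rec.name, "3p"))
        hits = scan(motifs, catalog, SearchParams(dg_cutoff=-10.0))
        got = {(h.mirna_name, h.end) for h in hits if h.stretch_len == 11}
        assert expected <= got

    def test_wobble_allowance_is_monotone(self):
        rng = random.Random(37)
        catalog = self._catalog([random_rna(rng, 21) for _ in range(6)])
        motifs = [motif_of(m) for m in ("GCGCAUGGCGC", "GGCAAUGCCGG", "CCGUAUGGCGG")]
        strict = scan(motifs, catalog, SearchParams(dg_cutoff=-5.0))
        loose = scan(
            motifs, catalog, SearchParams(dg_cutoff=-5.0, max_gu_5p=1, max_gu_3p=1)
        )
        key = lambda hits: {(id(h.motif), h.mirna_name, h.end) for h in hits}
        assert key(strict) <= key(loose)

    def test_numba_and_python_paths_agree(self):
        rng = random.Random(41)
        catalog = self._catalog(
            [random_rna(rng, 22) for _ in range(8)], [random_rna(rng, 21) for _ in range(4)]
        )
        motifs = [motif_of("GCGCAUGGCGC"), motif_of("CAUAAUGGGGU")]
        params = SearchParams(dg_cutoff=-8.0, max_gu_3p=1)
        a = scan(motifs, catalog, params, use_numba=True)
        b = scan(motifs, catalog, params, use_numba=False)
        assert [(h.mirna_name, h.end, h.stretch_len, h.dg37) for h in a] == [
            (h.mirna_name, h.end, h.stretch_len, h.dg37) for h in b
        ]

    def test_every_hit_satisfies_both_criteria(self):
        rng = random.Random(43)
        catalog = self._catalog([random_rna(rng, 22) for _ in range(10)])
        motifs = [motif_of(random_rna(rng, 8) + "AUG") for _ in range(10)]
        params = SearchParams(dg_cutoff=-6.0, max_gu_3p=1)
        for h in scan(motifs, catalog, params):
            assert h.stretch_len >= params.min_stretch
            assert h.dg37 <= params.dg_cutoff
            assert h.gu_count <= params.max_gu(h.end)
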