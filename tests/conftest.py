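"""Shared fixtures: tiny hand-written alignments, curated miRNAs, helpers."""

from __future__ import annotations

import random
from pathlib import Path

import pytest

from uaugscan.catalog import classify_conservation
from uaugscan.io import MiRnaRecord, UtrAlignmentPair, read_mirna_fasta

DATA = Path(__file__).parent / "data"
PKG_DATA = Path(__file__).parents[1] / "src" / "uaugscan" / "data"

# Independent brute-force helpers used as oracles in several test modules.

_PAIRS = {"AU", "UA", "CG", "GC"}
_WOBBLE = {"GU", "UG"}


def brute_force_max_stretch(motif: str, half: str, max_gu: int) -> int:
    """Exhaustive scan: extend a pairing run from every (i, j) start."""
    best = 0
    for i in range(len(motif)):
        for j in range(len(half) - 1, -1, -1):
            gu = 0
            length = 0
            a, b = i, j
            while a < len(motif) and b >= 0:
                p = motif[a] + half[b]
                if p in _WOBBLE:
                    gu += 1
                    if gu > max_gu:
                        break
                elif p not in _PAIRS:
                    break
                length += 1
                best = max(best, length)
                a += 1
                b -= 1
    return best


def random_rna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))


@pytest.fixture(scope="session")
def let7d() -> MiRnaRecord:
    return MiRnaRecord("hsa-let-7d", "AGAGGUAGUAGGUUGCAUAGUU")


@pytest.fixture(scope="session")
def mir31() -> MiRnaRecord:
    return MiRnaRecord("hsa-miR-31", "AGGCAAGAUGCUGGCAUAGCU")


@pytest.fixture(scope="session")
def curated_catalog():
    """The bundled curated two-species miRNA subset, classified."""
    records = read_mirna_fasta(PKG_DATA / "mirna_curated_subset.fasta")
    focal = [r for r in records if r.species_prefix == "hsa"]
    return classify_conservation(focal, records)


@pytest.fixture()
def simple_pair() -> UtrAlignmentPair:
    #               0123456789012
    human = "GCAUAAUGGGGUC"
    return UtrAlignmentPair(gene_id="geneA", human_aligned=human, mouse_aligned=human)


@pytest.fixture()
def gapped_pair() -> UtrAlignmentPair:
    # human ungapped: CCAUGCCGGUU ; mouse has a gap inside the motif span
    return UtrAlignmentPair(
        gene_id="geneB",
        human_aligned="CCAUGCCGGUU",
        mouse_aligned="CC-UGCCGGUU",
    )
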