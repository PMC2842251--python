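"""Synthetic datasets with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:
GC-rich 5'-UTR leader sequences aligned human/mouse with a controllable
per-column conservation rate, a controllable number of upstream AUGs per
UTR, a two-species miRNA catalog with a controllable conserved fraction,
and — optionally — binding sites planted on uAUG windows as exact reverse
complements of conserved miRNA 3'-half sequences.

All randomness flows from one root seed: stage ``k`` draws from the stream
``default_rng([seed, STAGE_k])``, so each stage is reproducible on its own
and the whole dataset is byte-stable across runs.

Planted windows overwrite only the 11-mer uAUG window, leaving flanks
untouched, and the mouse row is synchronised so the planted motif stays
conserved.  A miRNA half is *eligible* for planting only if (a) the reverse
complement of its 3'-terminal 11 nt carries AUG at window offset 4 and
(b) that perfect 11-bp duplex already passes the default energy screen —
so every planted site is recoverable by construction and recall on the
ground truth is exactly 1 for the un-mutated dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .catalog import CatalogPartition, classify_conservation, split_halves
from .energy import EnergyParameters, default_energy, duplex_free_energy
from .io import MiRnaRecord, UtrAlignmentPair
from .search import SearchParams
from .uaug import FLANK, FULL_MOTIF_LEN, find_uaugs

__all__ = [
    "GeneratorConfig",
    "PlantedSite",
    "gen_mirna_catalog",
    "gen_utr_alignments",
    "plant_sites",
    "generate_dataset",
]

_STAGE_CATALOG = 0
_STAGE_UTRS = 1
_STAGE_PLANT = 2

_NTS = np.array(list("ACGU"))
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic dataset.

    Defaults describe a leader-sequence corpus of the kind the analysis
    targets: GC-rich UTRs (gc_content 0.6) averaging two uAUGs each
    (Poisson, so ~68% of UTRs carry at most two), ~70% of miRNAs conserved,
    and human/mouse per-column identity 0.97 (≈70% of 11-mer windows fully
    conserved).

    ``site_competent_rate`` is part of the planting machinery: it embeds an
    AUG-complementary ``CAU`` triplet at the pairing register of a miRNA's
    3' half so that eligible planting candidates exist.  It defaults to 0
    because an unplanted (null) dataset must keep motifs and miRNAs
    independent; set it > 0 whenever ``plant_rate`` > 0.
    """

    n_utrs: int = 200
    utr_length_range: tuple[int, int] = (60, 300)
    column_conservation_rate: float = 0.97
    uaug_rate: float = 2.0
    n_mirnas: int = 70
    mirna_length_range: tuple[int, int] = (21, 23)
    conserved_mirna_fraction: float = 0.7
    plant_rate: float = 0.0
    gc_content: float = 0.6
    site_competent_rate: float = 0.0
    homolog_mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "column_conservation_rate",
            "conserved_mirna_fraction",
            "plant_rate",
            "gc_content",
            "site_competent_rate",
            "homolog_mutation_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("utr_length_range", "mirna_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"invalid {name}: {(lo, hi)}")


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted interaction (end is always the 3' half)."""

    gene_id: str
    aug_start: int
    mirna_name: str
    end: str = "3p"


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _NTS[rng.choice(4, size=n, p=p)]


def gen_mirna_catalog(config: GeneratorConfig) -> list[MiRnaRecord]:
    """Two-species mature miRNA catalog (focal ``hsa``, homologs ``mmu``).

    A ``conserved_mirna_fraction`` Bernoulli draw decides whether each focal
    base name also appears under the ``mmu`` prefix; homolog sequences are
    mutated at ``homolog_mutation_rate`` of positions, since conservation is
    a name-level property here, not a sequence-level one.  With probability
    ``site_competent_rate`` the 3'-half positions that map under reverse
    complementation to the AUG of a planted window are set to ``CAU``.
    """
    rng = np.random.default_rng([config.seed, _STAGE_CATALOG])
    lo, hi = config.mirna_length_range
    records: list[MiRnaRecord] = []
    for i in range(config.n_mirnas):
        n = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, n, config.gc_content)
        if n >= 18 and rng.random() < config.site_competent_rate:
            # window = revcomp(last 11 nt); AUG at window[4:7] <=> seq[n-7:n-4] == CAU
            seq[n - 7 : n - 4] = list("CAU")
        base = f"miR-s{i + 1:03d}"
        records.append(MiRnaRecord(name=f"hsa-{base}", sequence="".join(seq)))
        if rng.random() < config.conserved_mirna_fraction:
            hom = seq.copy()
            mut = rng.random(n) < config.homolog_mutation_rate
            for j in np.nonzero(mut)[0]:
                hom[j] = rng.choice(_NTS[_NTS != hom[j]])
            records.append(MiRnaRecord(name=f"mmu-{base}", sequence="".join(hom)))
    return records


def _strip_augs(seq: np.ndarray, rng: np.random.Generator) -> None:
    """Destroy every AUG occurrence in place (may loop: a fix can create one)."""
    while True:
        s = "".join(seq)
        starts = find_uaugs(s)
        if not starts:
            return
        for a in starts:
            seq[a + 1] = rng.choice(_NTS[_NTS != "U"])


def gen_utr_alignments(config: GeneratorConfig) -> list[UtrAlignmentPair]:
    """Gapless human/mouse alignment pairs with Poisson-injected uAUGs.

    The human sequence is random with the configured GC content, cleared of
    incidental AUGs, then exactly ``k ~ Poisson(uaug_rate)`` AUG triplets
    are written at non-overlapping positions.  The mouse row is a copy with
    independent per-column substitutions at ``1 − column_conservation_rate``.
    Generated alignments carry no gaps; gap handling is exercised by
    hand-written fixtures, not by this generator.
    """
    rng = np.random.default_rng([config.seed, _STAGE_UTRS])
    lo, hi = config.utr_length_range
    pairs: list[UtrAlignmentPair] = []
    for g in range(config.n_utrs):
        n = int(rng.integers(lo, hi + 1))
        human = _random_seq(rng, n, config.gc_content)
        _strip_augs(human, rng)
        k = min(int(rng.poisson(config.uaug_rate)), max(n // 6, 1))
        # place k AUGs at spaced positions; spacing 3 keeps injections disjoint
        for attempt in range(40):
            starts = np.sort(rng.choice(np.arange(0, n - 2), size=k, replace=False)) if k else []
            if all(b - a >= 3 for a, b in zip(starts, starts[1:])):
                break
        else:
            starts = np.arange(0, 3 * k, 3)
        trial = human.copy()
        for a in starts:
            trial[a : a + 3] = list("AUG")
        if len(find_uaugs("".join(trial))) != k:
            # injection boundary created a spurious AUG; repair and re-inject
            _strip_augs(trial, rng)
            for a in starts:
                trial[a : a + 3] = list("AUG")
        human = trial
        mouse = human.copy()
        sub = rng.random(n) >= config.column_conservation_rate
        for j in np.nonzero(sub)[0]:
            mouse[j] = rng.choice(_NTS[_NTS != mouse[j]])
        pairs.append(
            UtrAlignmentPair(
                gene_id=f"synthgene{g + 1:04d}",
                human_aligned="".join(human),
                mouse_aligned="".join(mouse),
            )
        )
    return pairs


def eligible_plant_halves(
    catalog: Sequence[MiRnaRecord],
    params: SearchParams | None = None,
    energy: EnergyParameters | None = None,
    focal_prefix: str = "hsa",
) -> list[tuple[str, str]]:
    """(miRNA name, 11-mer window) pairs usable for planting.

    The window is the reverse complement of the conserved miRNA's 3'-terminal
    11 nt; it must carry AUG at offset 4 and pass the default energy screen
    as a perfect duplex.
    """
    params = params or SearchParams()
    energy = energy or default_energy()
    focal = [r for r in catalog if r.species_prefix == focal_prefix]
    partition = classify_conservation(focal, list(catalog))
    out: list[tuple[str, str]] = []
    for rec in partition.conserved:
        three = split_halves(rec)[1].sequence
        if len(three) < FULL_MOTIF_LEN:
            continue
        s = three[-FULL_MOTIF_LEN:]
        window = _revcomp(s)
        if window[FLANK : FLANK + 3] != "AUG":
            continue
        if duplex_free_energy(window, s, energy) > params.dg_cutoff:
            continue
        out.append((rec.name, window))
    return out


def plant_sites(
    alignments: Sequence[UtrAlignmentPair],
    catalog: Sequence[MiRnaRecord],
    config: GeneratorConfig,
) -> tuple[list[UtrAlignmentPair], list[PlantedSite]]:
    """Overwrite a ``plant_rate`` fraction of full-window uAUGs with
    reverse-complement binding sites for eligible conserved miRNA 3' halves.

    Returns modified alignments plus the exact ground truth.  Windows that
    would overlap an earlier planted window are left untouched, and the
    mouse row is synchronised so planted motifs remain conserved.
    """
    rng = np.random.default_rng([config.seed, _STAGE_PLANT])
    candidates = eligible_plant_halves(catalog)
    if not candidates and config.plant_rate > 0:
        import warnings

        warnings.warn("no eligible miRNA 3' half for planting; ground truth is empty")
        return list(alignments), []
    truth: list[PlantedSite] = []
    out: list[UtrAlignmentPair] = []
    for pair in alignments:
        if "-" in pair.human_aligned:
            raise ValueError("plant_sites requires gapless generated alignments")
        human = np.array(list(pair.human_aligned))
        mouse = np.array(list(pair.mouse_aligned))
        planted_spans: list[tuple[int, int]] = []
        n = len(human)
        for aug in find_uaugs("".join(human)):
            lo, hi = aug - FLANK, aug + FLANK + 3
            if lo < 0 or hi > n:
                continue  # only full 11-mer windows are planted
            if any(lo < e and s < hi for s, e in planted_spans):
                continue
            if rng.random() >= config.plant_rate:
                continue
            name, window = candidates[int(rng.integers(len(candidates)))]
            human[lo:hi] = list(window)
            mouse[lo:hi] = list(window)
            planted_spans.append((lo, hi))
            truth.append(PlantedSite(gene_id=pair.gene_id, aug_start=aug, mirna_name=name))
        out.append(
            replace(pair, human_aligned="".join(human), mouse_aligned="".join(mouse))
        )
    return out, truth


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[list[UtrAlignmentPair], list[MiRnaRecord], list[PlantedSite]]:
    """Convenience wrapper: catalog, alignments and (optionally) planted sites."""
    catalog = gen_mirna_catalog(config)
    alignments = gen_utr_alignments(config)
    if config.plant_rate > 0:
        alignments, truth = plant_sites(alignments, catalog, config)
    else:
        truth = []
    return alignments, catalog, truth
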