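"""Shuffle-null construction and Z-test significance for interaction counts.

The null model re-runs the full two-step search after permuting the letters
of every mature miRNA (composition preserved, halves re-derived from the
shuffled sequence), and records per-stratum interaction counts over many
iterations.  Each iteration draws from its own counter-based RNG stream
seeded by (seed, iteration), so results do not depend on execution order.

Counts are (motif occurrence, miRNA, end) triples.  The null distribution
is summarised by its mean and sample standard deviation (n−1) and treated
as normal; significance is the one-sided upper-tail probability (excess of
interactions).  No multiple-testing correction is applied across strata by
default; a Bonferroni factor is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .catalog import FIVE_P, THREE_P, CatalogPartition, classify_conservation, shuffle_mirna
from .energy import EnergyParameters, default_energy
from .search import DuplexHit, SearchParams, scan
from .uaug import UAugMotif

__all__ = [
    "Stratum",
    "NullModel",
    "SignificanceResult",
    "FIG2_STRATA",
    "count_interactions",
    "null_distribution",
    "z_test",
    "significance_report",
]


@dataclass(frozen=True)
class Stratum:
    """A slice of the hit list; ``None`` fields mean 'any'."""

    end: str | None = None
    mirna_conserved: bool | None = None
    motif_conserved: bool | None = None

    def matches(self, hit: DuplexHit) -> bool:
        return (
            (self.end is None or hit.end == self.end)
            and (self.mirna_conserved is None or hit.mirna_conserved == self.mirna_conserved)
            and (self.motif_conserved is None or hit.motif.conserved == self.motif_conserved)
        )

    def label(self) -> str:
        parts = [
            self.end or "both",
            {True: "cons-mirna", False: "noncons-mirna", None: "all-mirna"}[self.mirna_conserved],
            {True: "cons-motif", False: "noncons-motif", None: "all-motif"}[self.motif_conserved],
        ]
        return "/".join(parts)


#: The eight strata of the genome-scale analysis: each miRNA end crossed with
#: miRNA conservation class (all motifs), and each end crossed with motif
#: conservation class (conserved miRNAs only).
FIG2_STRATA: tuple[Stratum, ...] = tuple(
    [Stratum(end=e, mirna_conserved=c) for e in (FIVE_P, THREE_P) for c in (True, False)]
    + [
        Stratum(end=e, mirna_conserved=True, motif_conserved=c)
        for e in (FIVE_P, THREE_P)
        for c in (True, False)
    ]
)


@dataclass
class NullModel:
    """Per-stratum shuffle-null counts with their normal summary."""

    iterations: int
    seed: int
    counts: np.ndarray
    mean: float
    sd: float


@dataclass
class SignificanceResult:
    stratum: Stratum
    observed: int
    null: NullModel
    z: float
    p_one_sided: float
    degenerate: bool = False


def count_interactions(hits: Iterable[DuplexHit], stratum: Stratum) -> int:
    """Number of (motif occurrence, miRNA, end) triples in the stratum."""
    return sum(1 for h in hits if stratum.matches(h))


def null_distribution(
    motifs: Sequence[UAugMotif],
    catalog: CatalogPartition,
    params: SearchParams | None = None,
    energy: EnergyParameters | None = None,
    iterations: int = 1000,
    seed: int = 0,
    strata: Sequence[Stratum] = FIG2_STRATA,
) -> dict[Stratum, NullModel]:
    """Shuffle every miRNA, re-scan, and collect per-stratum counts.

    Fully reproducible from ``seed``: iteration ``t`` uses the RNG stream
    ``default_rng([seed, t])`` regardless of execution order.
    """
    if iterations < 2:
        raise ValueError("need at least 2 iterations to estimate a standard deviation")
    params = params or SearchParams()
    energy = energy or default_energy()
    counts = np.zeros((iterations, len(strata)), dtype=np.int64)
    for t in range(iterations):
        rng = np.random.default_rng([seed, t])
        shuffled = CatalogPartition(
            conserved=[shuffle_mirna(r, rng) for r in catalog.conserved],
            non_conserved=[shuffle_mirna(r, rng) for r in catalog.non_conserved],
        )
        hits = scan(motifs, shuffled, params, energy)
        for s_idx, stratum in enumerate(strata):
            counts[t, s_idx] = count_interactions(hits, stratum)
    return {
        stratum: NullModel(
            iterations=iterations,
            seed=seed,
            counts=counts[:, s_idx].copy(),
            mean=float(counts[:, s_idx].mean()),
            sd=float(counts[:, s_idx].std(ddof=1)),
        )
        for s_idx, stratum in enumerate(strata)
    }


def z_test(observed: int, null: NullModel) -> tuple[float, float]:
    """One-sided upper-tail Z-test of an observed count against the null.

    With a degenerate null (sd == 0) the p-value is 0, 1 or 0.5 for observed
    above, below or equal to the null mean.
    """
    if null.sd == 0:
        if observed > null.mean:
            return float("inf"), 0.0
        if observed < null.mean:
            return float("-inf"), 1.0
        return 0.0, 0.5
    z = (observed - null.mean) / null.sd
    return z, float(norm.sf(z))


def empirical_p(observed: int, null: NullModel) -> float:
    """Diagnostic empirical upper-tail quantile, (1 + #{null >= obs}) / (n + 1)."""
    return (1.0 + int((null.counts >= observed).sum())) / (null.iterations + 1.0)


def significance_report(
    motifs: Sequence[UAugMotif],
    catalog: CatalogPartition,
    params: SearchParams | None = None,
    energy: EnergyParameters | None = None,
    iterations: int = 1000,
    seed: int = 0,
    strata: Sequence[Stratum] = FIG2_STRATA,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Observed counts, null summaries and Z-test p per stratum, as a table."""
    params = params or SearchParams()
    energy = energy or default_energy()
    observed_hits = scan(motifs, catalog, params, energy)
    nulls = null_distribution(motifs, catalog, params, energy, iterations, seed, strata)
    rows = []
    for stratum in strata:
        obs = count_interactions(observed_hits, stratum)
        null = nulls[stratum]
        z, p = z_test(obs, null)
        if bonferroni:
            p = min(1.0, p * len(strata))
        rows.append(
            {
                "stratum": stratum.label(),
                "observed": obs,
                "null_mean": round(null.mean, 4),
                "null_sd": round(null.sd, 4),
                "z": round(z, 4) if np.isfinite(z) else z,
                "p": p,
                "degenerate": null.sd == 0,
            }
        )
    return pd.DataFrame(rows)
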