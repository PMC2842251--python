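"""Nearest-neighbor free energy of a fully paired RNA duplex at 37 °C.

The duplex energy of an ungapped, antiparallel helix is

    dG37 = duplex_init + sum(stack energies over adjacent pair doublets)
           + terminal penalty at each helix end whose closing pair is not G·C

with stacking values from the Turner 2004 parameter set (Watson-Crick and
G·U wobble pairs).  Two conventions for the initiation term are bundled:

``turner2004-hybridization``
    ``duplex_init = 0``.  Energies follow the convention of duplex-screening
    tools, whose thresholds (such as the −14 kcal/mol screen used here)
    describe hybridization stability without the bimolecular initiation
    term.  This is the default for interaction screening.

``turner2004-duplex``
    ``duplex_init = +4.10`` kcal/mol, the standalone bimolecular duplex
    free energy; it reproduces ViennaRNA cofold evaluation (dangles off)
    exactly on fully paired duplexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

__all__ = [
    "EnergyParameters",
    "duplex_free_energy",
    "WC_PAIRS",
    "WOBBLE_PAIRS",
    "ALL_PAIRS",
]

WC_PAIRS = frozenset({"AU", "UA", "CG", "GC"})
WOBBLE_PAIRS = frozenset({"GU", "UG"})
ALL_PAIRS = WC_PAIRS | WOBBLE_PAIRS

_DATA_FILE = "stack_dg37_turner2004.tsv"


@dataclass(frozen=True)
class EnergyParameters:
    """Stacking table plus initiation and terminal-pair penalty, kcal/mol."""

    stack_table: Mapping[str, float]
    duplex_init: float
    terminal_au_penalty: float
    parameter_set_id: str

    def __post_init__(self) -> None:
        missing = [
            f"{p[0]}{q[0]}/{p[1]}{q[1]}"
            for p in sorted(ALL_PAIRS)
            for q in sorted(ALL_PAIRS)
            if f"{p[0]}{q[0]}/{p[1]}{q[1]}" not in self.stack_table
        ]
        if missing:
            raise ValueError(f"stack table incomplete; missing doublets {missing[:4]}...")

    @classmethod
    def _load_bundled(cls) -> tuple[dict[str, float], dict[str, str]]:
        stacks: dict[str, float] = {}
        meta: dict[str, str] = {}
        text = resources.files("uaugscan.data").joinpath(_DATA_FILE).read_text()
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("\t")
                meta[key] = value
                continue
            if line.startswith("doublet"):
                continue
            doublet, dg = line.split("\t")
            stacks[doublet] = float(dg)
        return stacks, meta

    @classmethod
    def turner2004(cls, convention: str = "hybridization") -> "EnergyParameters":
        """Load the bundled Turner 2004 table under the given convention."""
        stacks, meta = cls._load_bundled()
        terminal = float(meta.get("terminal_au", "0.50"))
        if convention == "hybridization":
            init = 0.0
        elif convention == "duplex":
            init = float(meta.get("duplex_init", "4.10"))
        else:
            raise ValueError(f"unknown convention {convention!r}")
        return cls(
            stack_table=stacks,
            duplex_init=init,
            terminal_au_penalty=terminal,
            parameter_set_id=f"{meta.get('parameter_set_id', 'turner2004')}-{convention}",
        )


_DEFAULT: list[EnergyParameters] = []


def default_energy() -> EnergyParameters:
    """The bundled Turner 2004 table under the hybridization convention."""
    if not _DEFAULT:
        _DEFAULT.append(EnergyParameters.turner2004("hybridization"))
    return _DEFAULT[0]


def duplex_free_energy(motif_sub: str, half_sub: str, params: EnergyParameters) -> float:
    """dG37 (kcal/mol) of the fully paired antiparallel duplex of two subsequences.

    ``motif_sub`` and ``half_sub`` are both written 5'→3'; position ``i`` of
    the motif pairs position ``n−1−i`` of the half.  Every position must form
    a Watson-Crick or G·U pair.
    """
    n = len(motif_sub)
    if n == 0 or n != len(half_sub):
        raise ValueError("subsequences must be non-empty and of equal length")
    bottom = half_sub[::-1]  # now 3'->5' under the motif
    for t, b in zip(motif_sub, bottom):
        if t + b not in ALL_PAIRS:
            raise ValueError(f"unpairable position {t}·{b} in duplex")
    dg = params.duplex_init
    for i in range(n - 1):
        dg += params.stack_table[f"{motif_sub[i]}{motif_sub[i+1]}/{bottom[i]}{bottom[i+1]}"]
    for i in (0, n - 1):
        if motif_sub[i] + bottom[i] not in ("GC", "CG"):
            dg += params.terminal_au_penalty
    return round(dg, 10)
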