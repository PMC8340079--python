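"""In-silico proteolysis and glycosylation-site detection.

Trypsin cleaves C-terminal to Lys/Arg except before Pro ("fully specific"
classical rule); peptide coordinates are 1-based inclusive.  N-glycosylation
sites are sequons N-X-[S/T] with X != P.  O-glycosylation in Ser/Thr-rich
stretches cannot be localized to single residues from intact or peptide-level
data, so O-sites are modeled as *regions* with a glycan-count capacity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Literal

__all__ = [
    "PeptideSpan",
    "GlycosylationSite",
    "tryptic_digest",
    "find_sequons",
    "max_glycans_at_level",
]


@dataclass(frozen=True)
class PeptideSpan:
    """A proteolytic peptide with 1-based inclusive coordinates."""

    parent: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(f"span {self.start}-{self.end} inconsistent with sequence length")


@dataclass(frozen=True)
class GlycosylationSite:
    """An N-site (single sequon Asn) or an O-region (residue range)."""

    subunit: str
    kind: Literal["N", "O"]
    start: int
    end: int
    capacity: int = 1

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError("site capacity must be >= 1")
        if self.end < self.start:
            raise ValueError("site end before start")

    @property
    def label(self) -> str:
        if self.kind == "N":
            return f"{self.subunit}:N{self.start}"
        return f"{self.subunit}:O{self.start}-{self.end}"


def _cleavage_points(sequence: str) -> list[int]:
    """0-based indices *after* which trypsin cleaves (K/R not before P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(sequence: str, max_missed: int = 0, parent: str = "protein") -> list[PeptideSpan]:
    """Fully specific tryptic digest with up to ``max_missed`` missed cleavages."""
    points = _cleavage_points(sequence)
    # fragment boundaries as 0-based half-open [start, end)
    starts = [0] + [p + 1 for p in points]
    ends = [p + 1 for p in points] + [len(sequence)]
    peptides = []
    n = len(starts)
    for i in range(n):
        for m in range(min(max_missed, n - 1 - i) + 1):
            s, e = starts[i], ends[i + m]
            peptides.append(
                PeptideSpan(
                    parent=parent,
                    start=s + 1,
                    end=e,
                    sequence=sequence[s:e],
                    missed_cleavages=m,
                )
            )
    return peptides


_SEQUON_RE = re.compile(r"N(?=[^P][ST])")


def find_sequons(sequence: str, subunit: str = "protein") -> list[GlycosylationSite]:
    """Positions (1-based) of N-X-[S/T] sequons with X != P."""
    return [
        GlycosylationSite(subunit=subunit, kind="N", start=m.start() + 1, end=m.start() + 1)
        for m in _SEQUON_RE.finditer(sequence)
    ]


def max_glycans_at_level(sites: Iterable[GlycosylationSite]) -> int:
    """Maximum number of glycans the intact chain can carry: sum of capacities."""
    return sum(site.capacity for site in sites)
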