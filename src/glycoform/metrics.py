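"""Abundance-weighted glycosylation quality attributes.

Two critical quality attributes (CQAs) are computed at any structural level
(glycopeptide, subunit, dimer) from weighted glycoforms:

* degree of sialylation — observed Neu5Ac divided by the maximum number the
  glycoform could carry (one per complex/hybrid N-glycan antenna, two per
  O-glycan core), averaged over glycoforms with abundance weights;
* degree of core fucosylation — core-fucosylated N-glycans divided by the
  number of N-glycans, weighted the same way.

Glycoforms for which the respective maximum is zero (e.g. pure high-mannose
species for sialylation, N-free glycoforms for fucosylation) carry no
information about the attribute and are excluded from the weighted mean;
``unmodified`` sites contribute nothing (occupancy is a separate statistic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .chem import GlycanClass, GlycanSpecies
from .library import GlycoformLibraryEntry

__all__ = [
    "CqaResult",
    "UndefinedMetricError",
    "degree_of_sialylation",
    "degree_of_core_fucosylation",
    "cqa_for_entries",
    "compare_batches",
]


class UndefinedMetricError(ValueError):
    """Raised when no glycoform in the input constrains the attribute."""


@dataclass(frozen=True)
class CqaResult:
    level: str  # glycopeptide | subunit | dimer
    target: str
    sialylation: float
    core_fucosylation: float
    weight_used: float

    def __post_init__(self) -> None:
        for v in (self.sialylation, self.core_fucosylation):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"degree {v} outside [0, 1]")


WeightedGlycoform = tuple[float, Sequence[GlycanSpecies]]


def _as_weighted(entries: Iterable[GlycoformLibraryEntry | WeightedGlycoform]):
    for e in entries:
        if isinstance(e, GlycoformLibraryEntry):
            yield e.abundance, e.species
        else:
            yield e


def _n_glycans(species: Sequence[GlycanSpecies]) -> list[GlycanSpecies]:
    return [sp for sp in species if sp.glycan_class is GlycanClass.N]


def degree_of_sialylation(
    entries: Iterable[GlycoformLibraryEntry | WeightedGlycoform],
) -> float:
    """Abundance-weighted mean of Neu5Ac count over maximum Neu5Ac capacity.

    Capacity per glycoform: one Neu5Ac per N-glycan antenna plus two per
    O-glycan core.  Non-antennary N-glycans (high-mannose) add no capacity.
    """
    num = 0.0
    weight = 0.0
    any_input = False
    for w, species in _as_weighted(entries):
        any_input = True
        max_sia = sum(sp.antennae for sp in _n_glycans(species)) + 2 * sum(
            sp.cores for sp in species if sp.glycan_class is GlycanClass.O
        )
        if max_sia == 0:
            continue
        observed = sum(sp.neu5ac_count for sp in species)
        num += w * min(observed / max_sia, 1.0)
        weight += w
    if not any_input or weight == 0.0:
        raise UndefinedMetricError(
            "degree of sialylation undefined: no glycoform has sialylation capacity"
        )
    return num / weight


def degree_of_core_fucosylation(
    entries: Iterable[GlycoformLibraryEntry | WeightedGlycoform],
) -> float:
    """Abundance-weighted fraction of N-glycans carrying a core fucose."""
    num = 0.0
    weight = 0.0
    any_input = False
    for w, species in _as_weighted(entries):
        any_input = True
        n_glycans = _n_glycans(species)
        if not n_glycans:
            continue
        num += w * sum(1 for sp in n_glycans if sp.core_fucose) / len(n_glycans)
        weight += w
    if not any_input or weight == 0.0:
        raise UndefinedMetricError(
            "degree of core fucosylation undefined: no glycoform carries an N-glycan"
        )
    return num / weight


def cqa_for_entries(
    entries: Sequence[GlycoformLibraryEntry], level: str, target: str
) -> CqaResult:
    """Bundle both degrees for a library of weighted glycoforms."""
    return CqaResult(
        level=level,
        target=target,
        sialylation=degree_of_sialylation(entries),
        core_fucosylation=degree_of_core_fucosylation(entries),
        weight_used=sum(e.abundance for e in entries),
    )


def compare_batches(
    results_a: Sequence[CqaResult], results_b: Sequence[CqaResult]
) -> pd.DataFrame:
    """Tabular batch comparison keyed by (level, target).

    Keys present in only one batch yield warning rows with missing deltas
    rather than failing the whole comparison.
    """
    index_a = {(r.level, r.target): r for r in results_a}
    index_b = {(r.level, r.target): r for r in results_b}
    rows = []
    for key in sorted(set(index_a) | set(index_b)):
        level, target = key
        ra, rb = index_a.get(key), index_b.get(key)
        row: dict = {"level": level, "target": target}
        if ra is None or rb is None:
            row["warning"] = "missing in batch " + ("A" if ra is None else "B")
            present = ra or rb
            row["sialylation_a"] = ra.sialylation if ra else float("nan")
            row["sialylation_b"] = rb.sialylation if rb else float("nan")
            row["core_fucosylation_a"] = ra.core_fucosylation if ra else float("nan")
            row["core_fucosylation_b"] = rb.core_fucosylation if rb else float("nan")
            row["sialylation_delta"] = float("nan")
            row["core_fucosylation_delta"] = float("nan")
            row["sialylation_rel_delta"] = float("nan")
            row["core_fucosylation_rel_delta"] = float("nan")
            assert present is not None
        else:
            ds = rb.sialylation - ra.sialylation
            df_ = rb.core_fucosylation - ra.core_fucosylation
            row.update(
                warning="",
                sialylation_a=ra.sialylation,
                sialylation_b=rb.sialylation,
                sialylation_delta=ds,
                sialylation_rel_delta=ds / ra.sialylation if ra.sialylation else float("nan"),
                core_fucosylation_a=ra.core_fucosylation,
                core_fucosylation_b=rb.core_fucosylation,
                core_fucosylation_delta=df_,
                core_fucosylation_rel_delta=(
                    df_ / ra.core_fucosylation if ra.core_fucosylation else float("nan")
                ),
            )
        rows.append(row)
    return pd.DataFrame(rows)
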