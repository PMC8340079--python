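"""Site-specific quantitative glycan libraries.

A :class:`SiteGlycanLibrary` maps each glycosylation site (or O-region) to a
categorical distribution over glycan species.  The reserved species
``unmodified`` encodes partial site occupancy, so macroheterogeneity and
microheterogeneity fall out of the same combinatorics.  In-silico enzymatic
transforms (sialidase, PNGase F) rewrite species and merge the ones the
transform makes identical, keeping each site's abundances normalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import (
    EMPTY_COMPOSITION,
    GlycanClass,
    GlycanComposition,
    GlycanSpecies,
    MassMode,
    deamidated_unmodified,
    desialylate_species,
    parse_glycan_name,
)

__all__ = [
    "SiteGlycanLibrary",
    "GlycoformLibraryEntry",
    "TruncationResult",
    "LibraryError",
    "load_library",
    "library_from_mapping",
    "desialylate_library",
    "deNglycosylate_library",
    "truncate_by_cutoff",
    "count_candidate_glycoforms",
]


class LibraryError(ValueError):
    pass


@dataclass(frozen=True)
class SiteGlycanLibrary:
    """Ordered per-site categorical distributions over glycan species.

    ``sites`` maps site label -> tuple of (species, relative abundance);
    abundances at each site sum to 1 after normalization.
    """

    sites: dict[str, tuple[tuple[GlycanSpecies, float], ...]]
    mass_mode: MassMode = MassMode.monoisotopic
    source_level: str = "glycopeptide"

    @property
    def site_names(self) -> tuple[str, ...]:
        return tuple(self.sites)

    def species_at(self, site: str) -> tuple[GlycanSpecies, ...]:
        return tuple(sp for sp, _ in self.sites[site])

    def abundance(self, site: str, species_name: str) -> float:
        for sp, w in self.sites[site]:
            if sp.name == species_name:
                return w
        raise KeyError(species_name)


def _normalize(entries: Sequence[tuple[GlycanSpecies, float]]) -> tuple[tuple[GlycanSpecies, float], ...]:
    total = sum(w for _, w in entries)
    if total <= 0:
        raise LibraryError("site abundances sum to zero")
    return tuple((sp, w / total) for sp, w in entries)


def _merge_duplicates(entries: Iterable[tuple[GlycanSpecies, float]]) -> list[tuple[GlycanSpecies, float]]:
    merged: dict[str, list] = {}
    for sp, w in entries:
        key = sp.name
        if key in merged:
            merged[key][1] += w
        else:
            merged[key] = [sp, w]
    return [(sp, w) for sp, w in merged.values()]


def library_from_mapping(
    mapping: Mapping[str, Sequence[tuple[GlycanSpecies | str, float]]],
    mass_mode: MassMode = MassMode.monoisotopic,
    source_level: str = "glycopeptide",
) -> SiteGlycanLibrary:
    """Build a normalized library from ``{site: [(species|name, weight), ...]}``."""
    sites = {}
    for site, entries in mapping.items():
        parsed = []
        for sp, w in entries:
            if isinstance(sp, str):
                sp = parse_glycan_name(sp)
            if w < 0:
                raise LibraryError(f"negative abundance for {sp.name!r} at {site!r}")
            parsed.append((sp, float(w)))
        sites[site] = _normalize(_merge_duplicates(parsed))
    return SiteGlycanLibrary(sites=sites, mass_mode=mass_mode, source_level=source_level)


def load_library(
    table,
    mass_mode: MassMode = MassMode.monoisotopic,
    known_sites: Sequence[str] | None = None,
) -> SiteGlycanLibrary:
    """Load a site library from a delimited-text file or DataFrame.

    The table must carry columns ``site``, ``glycan``, ``abundance``.
    Duplicate (site, glycan) rows are summed before per-site normalization.
    ``known_sites``, when given, restricts and orders the accepted sites;
    rows naming any other site are rejected.
    """
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.read_csv(table, sep="\t")
    missing = {"site", "glycan", "abundance"} - set(df.columns)
    if missing:
        raise LibraryError(f"library table lacks column(s) {sorted(missing)}")
    if (df["abundance"] < 0).any():
        bad = df.loc[df["abundance"] < 0].iloc[0]
        raise LibraryError(f"negative abundance for {bad['glycan']!r} at {bad['site']!r}")
    if known_sites is not None:
        unknown = set(df["site"]) - set(known_sites)
        if unknown:
            raise LibraryError(f"unknown site(s) {sorted(unknown)}")
        site_order = [s for s in known_sites if s in set(df["site"])]
    else:
        site_order = list(dict.fromkeys(df["site"]))
    mapping = {
        site: [(g, a) for g, a in zip(sub["glycan"], sub["abundance"])]
        for site, sub in ((s, df[df["site"] == s]) for s in site_order)
    }
    return library_from_mapping(mapping, mass_mode=mass_mode)


# ---------------------------------------------------------------------------
# in-silico enzymatic transforms
# ---------------------------------------------------------------------------


def desialylate_library(lib: SiteGlycanLibrary) -> SiteGlycanLibrary:
    """In-silico sialidase digest: strip Neu5Ac everywhere and re-merge.

    Species made identical by the transform (A2S2 and A2G2 both become A2G2)
    are merged with summed abundances; per-site sums remain 1.
    """
    sites = {
        site: _normalize(_merge_duplicates((desialylate_species(sp), w) for sp, w in entries))
        for site, entries in lib.sites.items()
    }
    return replace(lib, sites=sites)


def deNglycosylate_library(lib: SiteGlycanLibrary) -> SiteGlycanLibrary:
    """In-silico PNGase F digest.

    Every N-class species becomes ``unmodified`` carrying a deamidation flag
    (PNGase F converts the occupied Asn to Asp, +0.984 Da); sites that were
    never occupied keep plain ``unmodified``.  O-regions are untouched.
    """
    sites = {}
    for site, entries in lib.sites.items():
        out = []
        for sp, w in entries:
            if sp.glycan_class is GlycanClass.N:
                out.append((deamidated_unmodified(), w))
            else:
                out.append((sp, w))
        sites[site] = _normalize(_merge_duplicates(out))
    return replace(lib, sites=sites)


# ---------------------------------------------------------------------------
# whole-chain glycoform libraries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GlycoformLibraryEntry:
    """A whole-chain glycoform with its fractional abundance.

    ``label`` joins per-site species names in site order ("A2S1G1/A2S2");
    ``species`` keeps the structured per-site tuple for metric computation.
    Fractional abundances over a library sum to <= 1 (cutoff truncation
    removes mass without renormalizing).
    """

    label: str
    species: tuple[GlycanSpecies, ...]
    composition: GlycanComposition
    abundance: float
    site_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("negative fractional abundance")

    @property
    def deamidation_count(self) -> int:
        return sum(1 for sp in self.species if sp.deamidated)


@dataclass(frozen=True)
class TruncationResult:
    """Entries kept by an abundance cutoff plus coverage bookkeeping."""

    entries: tuple[GlycoformLibraryEntry, ...]
    retained_count: int
    coverage: float  # retained share of the pre-truncation total abundance
    cutoff: float


def truncate_by_cutoff(
    entries: Sequence[GlycoformLibraryEntry], cutoff: float
) -> TruncationResult:
    """Keep glycoforms with fractional abundance >= ``cutoff``.

    Abundances are *not* renormalized; ``coverage`` reports the retained
    fraction of the full pre-truncation total.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    total = sum(e.abundance for e in entries)
    kept = tuple(e for e in entries if e.abundance >= cutoff) if cutoff > 0 else tuple(entries)
    coverage = (sum(e.abundance for e in kept) / total) if total > 0 else 0.0
    return TruncationResult(
        entries=kept, retained_count=len(kept), coverage=coverage, cutoff=cutoff
    )


def count_candidate_glycoforms(lib: SiteGlycanLibrary) -> int:
    """Unconstrained combinatorial glycoform count: product of site sizes."""
    return math.prod(len(entries) for entries in lib.sites.values())
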