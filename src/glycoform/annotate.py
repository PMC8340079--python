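"""Two-stage glycoform annotation of deconvoluted neutral-mass spectra.

Stage 1 decomposes the residual mass (peak mass minus backbone mass,
considering variable-modification alternatives) into monosaccharide
compositions within per-unit bounds and a mass tolerance.  Stage 2 searches
the site-specific glycan library for per-site species tuples whose summed
composition matches a stage-1 hit exactly; the product of the site-specific
relative abundances is the raw score, and hit scores are the raw scores
normalized to 100% over all assignments of a peak — the estimated
contribution of each isobaric glycoform to the peak's intensity.

Assignments are ranked by descending hit score, then ascending absolute mass
error, then lexicographic glycoform label.  Sodium-adduct satellites
(+21.982 Da from an annotated peak) and the −1 Da deconvolution artifact of
sulfur-rich proteins are detected and flagged, never silently corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .chem import (
    GlycanComposition,
    GlycanSpecies,
    MassMode,
    ProteinBackbone,
    backbone_mass,
    composition_mass,
    modification_mass,
    monosaccharide_mass,
)
from .library import GlycoformLibraryEntry, SiteGlycanLibrary

__all__ = [
    "Peak",
    "Tolerance",
    "CompositionBounds",
    "CompositionHit",
    "GlycoformAssignment",
    "AnnotatedPeak",
    "decompose_mass",
    "assign_sites",
    "annotate_spectrum",
    "fractional_abundances",
    "abundance_coverage",
]

# mass of one proton-equivalent shift used by the -1 Da artifact rescue
MINUS1_DA = 1.00235
# sodium adduct offsets per mass mode (Na - H)
_NA_OFFSET = {
    MassMode.monoisotopic: modification_mass("sodium_adduct", MassMode.monoisotopic),
    MassMode.average: modification_mass("sodium_adduct", MassMode.average),
}


@dataclass(frozen=True)
class Peak:
    """A deconvoluted neutral-mass peak."""

    mass: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("peak mass must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be >= 0")


@dataclass(frozen=True)
class Tolerance:
    """A symmetric mass tolerance in ppm or Da."""

    value: float
    unit: str = "ppm"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("tolerance must be positive")
        if self.unit not in ("ppm", "Da"):
            raise ValueError(f"unknown tolerance unit {self.unit!r}")

    def window_da(self, reference_mass: float) -> float:
        """Absolute half-window in Da at the given reference mass."""
        if self.unit == "Da":
            return self.value
        return self.value * reference_mass / 1e6

    def error(self, observed: float, theoretical: float) -> float:
        """Signed error in this tolerance's unit."""
        if self.unit == "Da":
            return observed - theoretical
        return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class CompositionBounds:
    """Per-unit maxima for the stage-1 composition search.

    Defaults are generous for a ~12 kDa glycan load on a dimeric
    glycohormone; the search is complete within these bounds.
    """

    hex: int = 40
    hexnac: int = 40
    fuc: int = 8
    neu5ac: int = 16

    @classmethod
    def from_library(cls, lib: SiteGlycanLibrary) -> "CompositionBounds":
        """Exact per-unit capacity of a site library (sum of site maxima)."""
        def cap(unit: str) -> int:
            return sum(
                max(getattr(sp.composition, unit) for sp, _ in entries)
                for entries in lib.sites.values()
            )

        return cls(hex=cap("hex"), hexnac=cap("hexnac"), fuc=cap("fuc"), neu5ac=cap("neu5ac"))


@dataclass(frozen=True)
class CompositionHit:
    """A stage-1 result: a composition matching the residual mass."""

    composition: GlycanComposition
    theoretical_mass: float  # residual-scale mass of the composition
    error: float  # signed, in the tolerance's unit


@dataclass(frozen=True)
class GlycoformAssignment:
    """A stage-2 result: one per-site species tuple explaining a peak."""

    species: tuple[GlycanSpecies, ...]
    site_names: tuple[str, ...]
    composition: GlycanComposition
    theoretical_mass: float  # full molecule (backbone variant + glycans)
    error: float  # signed, tolerance unit
    raw_score: float
    hit_score: float  # percent, normalized to 100 over the peak
    oxidations: int = 0
    deamidations: int = 0
    # dimer annotation: (chain A glycoform label, chain B glycoform label)
    chain_labels: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        if self.chain_labels:
            return " // ".join(self.chain_labels)
        return "/".join(sp.name for sp in self.species)


@dataclass(frozen=True)
class AnnotatedPeak:
    """A peak with its ranked glycoform assignments and diagnostic flags."""

    peak: Peak
    assignments: tuple[GlycoformAssignment, ...]
    flags: frozenset[str] = frozenset()
    near_miss: CompositionHit | None = None
    adduct_parent_mass: float | None = None

    @property
    def annotated(self) -> bool:
        return len(self.assignments) > 0

    @property
    def top(self) -> GlycoformAssignment | None:
        return self.assignments[0] if self.assignments else None


# ---------------------------------------------------------------------------
# stage 1: composition decomposition
# ---------------------------------------------------------------------------


def decompose_mass(
    residual: float,
    tol: Tolerance,
    bounds: CompositionBounds = CompositionBounds(),
    mode: MassMode = MassMode.monoisotopic,
    reference_mass: float | None = None,
) -> list[CompositionHit]:
    """Enumerate every bounded composition whose mass matches ``residual``.

    For ppm tolerances the absolute window is computed at ``reference_mass``
    (the intact molecular mass during annotation); it defaults to the
    residual itself when the function is used standalone.  The enumeration
    is complete with respect to brute force within the bounds.
    """
    ref = reference_mass if reference_mass is not None else residual
    window = tol.window_da(max(ref, 0.0))
    if residual < -window:
        return []
    m_hex = monosaccharide_mass("Hex", mode)
    m_hexnac = monosaccharide_mass("HexNAc", mode)
    m_fuc = monosaccharide_mass("Fuc", mode)
    m_neu = monosaccharide_mass("Neu5Ac", mode)

    hits = []
    # nested loops with mass pruning; the innermost count is solved directly
    for n_neu in range(bounds.neu5ac + 1):
        rem1 = residual - n_neu * m_neu
        if rem1 < -window:
            break
        for n_hexnac in range(bounds.hexnac + 1):
            rem2 = rem1 - n_hexnac * m_hexnac
            if rem2 < -window:
                break
            for n_hex in range(bounds.hex + 1):
                rem3 = rem2 - n_hex * m_hex
                if rem3 < -window:
                    break
                lo = math.ceil((rem3 - window) / m_fuc)
                hi = math.floor((rem3 + window) / m_fuc)
                for n_fuc in range(max(lo, 0), min(hi, bounds.fuc) + 1):
                    comp = GlycanComposition(n_hex, n_hexnac, n_fuc, n_neu)
                    theo = composition_mass(comp, mode)
                    ref_for_error = ref if reference_mass is not None else max(theo, 1e-12)
                    err = (
                        residual - theo
                        if tol.unit == "Da"
                        else 1e6 * (residual - theo) / ref_for_error
                    )
                    hits.append(CompositionHit(comp, theo, err))
    hits.sort(key=lambda h: (abs(h.error), h.composition))
    return hits


def nearest_composition(
    residual: float,
    bounds: CompositionBounds = CompositionBounds(),
    mode: MassMode = MassMode.monoisotopic,
    search_window_da: float = 2.0,
) -> CompositionHit | None:
    """Best near-miss composition (smallest |mass error| in Da) for diagnostics."""
    hits = decompose_mass(
        residual,
        Tolerance(search_window_da, "Da"),
        bounds=bounds,
        mode=mode,
        reference_mass=residual,
    )
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# stage 2: library-constrained site assignment
# ---------------------------------------------------------------------------


def _site_entries(lib: SiteGlycanLibrary) -> list[tuple[str, tuple[tuple[GlycanSpecies, float], ...]]]:
    return list(lib.sites.items())


def _suffix_maxima(sites: Sequence[tuple[str, tuple[tuple[GlycanSpecies, float], ...]]]):
    """Per-suffix component-wise maxima used to prune the tuple search."""
    n = len(sites)
    maxima = [(0, 0, 0, 0, 0)] * (n + 1)  # hex, hexnac, fuc, neu5ac, deamid
    for i in range(n - 1, -1, -1):
        entries = sites[i][1]
        h = max(sp.composition.hex for sp, _ in entries)
        hn = max(sp.composition.hexnac for sp, _ in entries)
        f = max(sp.composition.fuc for sp, _ in entries)
        nu = max(sp.composition.neu5ac for sp, _ in entries)
        d = max(int(sp.deamidated) for sp, _ in entries)
        prev = maxima[i + 1]
        maxima[i] = (prev[0] + h, prev[1] + hn, prev[2] + f, prev[3] + nu, prev[4] + d)
    return maxima


def assign_sites(
    target: GlycanComposition,
    lib: SiteGlycanLibrary,
    deamidations: int | None = None,
) -> list[tuple[tuple[GlycanSpecies, ...], float]]:
    """Enumerate per-site species tuples summing exactly to ``target``.

    Returns ``(species_tuple, raw_score)`` pairs where the raw score is the
    product of the site-specific relative abundances.  ``deamidations``
    restricts results to tuples carrying exactly that many deamidated
    species (PNGase F bookkeeping); ``None`` accepts any count.
    """
    sites = _site_entries(lib)
    maxima = _suffix_maxima(sites)
    results: list[tuple[tuple[GlycanSpecies, ...], float]] = []

    def recurse(i: int, rem: GlycanComposition, rem_deam: int | None, chosen: list, score: float):
        if i == len(sites):
            if rem == GlycanComposition() and (rem_deam in (None, 0)):
                results.append((tuple(chosen), score))
            return
        mx = maxima[i]
        if rem.hex > mx[0] or rem.hexnac > mx[1] or rem.fuc > mx[2] or rem.neu5ac > mx[3]:
            return
        if rem_deam is not None and rem_deam > mx[4]:
            return
        for sp, w in sites[i][1]:
            c = sp.composition
            if c.hex > rem.hex or c.hexnac > rem.hexnac or c.fuc > rem.fuc or c.neu5ac > rem.neu5ac:
                continue
            nd = rem_deam
            if nd is not None:
                nd = nd - int(sp.deamidated)
                if nd < 0:
                    continue
            chosen.append(sp)
            recurse(
                i + 1,
                GlycanComposition(
                    rem.hex - c.hex, rem.hexnac - c.hexnac, rem.fuc - c.fuc, rem.neu5ac - c.neu5ac
                ),
                nd,
                chosen,
                score * w,
            )
            chosen.pop()

    recurse(0, target, deamidations, [], 1.0)
    return results


# ---------------------------------------------------------------------------
# whole-spectrum annotation
# ---------------------------------------------------------------------------


def _backbone_variants(backbone: ProteinBackbone, lib: SiteGlycanLibrary, mode: MassMode):
    """(oxidations, deamidations, base mass) alternatives to consider.

    Deamidation counts range over what the library can supply (sites holding
    a deamidated species); oxidation over the backbone's allowance.
    """
    base = backbone_mass(backbone, mode)
    m_ox = modification_mass("oxidation", mode)
    m_deam = modification_mass("deamidation", mode)
    max_deam = sum(
        1 for entries in lib.sites.values() if any(sp.deamidated for sp, _ in entries)
    )
    variants = []
    for ox in range(backbone.max_oxidations + 1):
        for deam in range(max_deam + 1):
            variants.append((ox, deam, base + ox * m_ox + deam * m_deam))
    return variants


def _rank_key(a: GlycoformAssignment):
    return (-a.hit_score, abs(a.error), a.label)


def annotate_spectrum(
    peaks: Sequence[Peak],
    backbone: ProteinBackbone,
    lib: SiteGlycanLibrary,
    tol: Tolerance,
    mode: MassMode = MassMode.monoisotopic,
    bounds: CompositionBounds | None = None,
    detect_adducts: bool = True,
    rescue_minus1da: bool = False,
    report_near_miss: bool = True,
) -> list[AnnotatedPeak]:
    """Annotate every peak of a deconvoluted spectrum against a site library.

    Stage-1 bounds default to the library's exact per-unit capacity, so the
    search is complete over everything stage 2 could assign.  Unannotated
    peaks are flagged, never dropped; they carry their best near-miss
    composition for diagnosis (e.g. deconvolution artifacts).
    """
    if MassMode(mode) is not MassMode(lib.mass_mode):
        raise ValueError(
            f"mass-mode mismatch: spectrum {mode} vs library {lib.mass_mode}"
        )
    mode = MassMode(mode)
    if bounds is None:
        bounds = CompositionBounds.from_library(lib)
    variants = _backbone_variants(backbone, lib, mode)
    site_names = lib.site_names

    def annotate_one(peak_mass: float) -> list[GlycoformAssignment]:
        collected: dict[tuple, list] = {}
        for ox, deam, base in variants:
            residual = peak_mass - base
            hits = decompose_mass(
                residual, tol, bounds=bounds, mode=mode, reference_mass=peak_mass
            )
            for hit in hits:
                for species_tuple, raw in assign_sites(hit.composition, lib, deamidations=deam):
                    theo = base + hit.theoretical_mass
                    err = tol.error(peak_mass, theo)
                    key = tuple(sp.name for sp in species_tuple)
                    # oxidation variants of one glycoform are one proteoform:
                    # sum raw scores, keep the closest-mass representative
                    rec = collected.get(key)
                    if rec is None:
                        collected[key] = [species_tuple, hit.composition, theo, err, raw, ox, deam]
                    else:
                        rec[4] += raw
                        if abs(err) < abs(rec[3]):
                            rec[2], rec[3], rec[5], rec[6] = theo, err, ox, deam
        total_raw = sum(rec[4] for rec in collected.values())
        assignments = [
            GlycoformAssignment(
                species=rec[0],
                site_names=site_names,
                composition=rec[1],
                theoretical_mass=rec[2],
                error=rec[3],
                raw_score=rec[4],
                hit_score=100.0 * rec[4] / total_raw if total_raw > 0 else 0.0,
                oxidations=rec[5],
                deamidations=rec[6],
            )
            for rec in collected.values()
        ]
        assignments.sort(key=_rank_key)
        return assignments

    annotated: list[AnnotatedPeak] = []
    for peak in peaks:
        assignments = annotate_one(peak.mass)
        flags: set[str] = set()
        if not assignments and rescue_minus1da:
            assignments = annotate_one(peak.mass + MINUS1_DA)
            if assignments:
                flags.add("minus1da_artifact")
        near = None
        if not assignments:
            flags.add("unannotated")
            if report_near_miss:
                base0 = variants[0][2]
                window = max(2.0, 10.0 * tol.window_da(peak.mass))
                near = nearest_composition(
                    peak.mass - base0, bounds=bounds, mode=mode, search_window_da=window
                )
        annotated.append(
            AnnotatedPeak(peak=peak, assignments=tuple(assignments), flags=frozenset(flags), near_miss=near)
        )

    if detect_adducts:
        annotated = _flag_sodium_adducts(annotated, tol, mode)
    return annotated


def _flag_sodium_adducts(
    annotated: list[AnnotatedPeak], tol: Tolerance, mode: MassMode
) -> list[AnnotatedPeak]:
    """Flag peaks sitting +21.982 Da above an annotated peak.

    Satellites inherit the parent's assignments (flagged) when they have none
    of their own; their intensity is *not* folded into the parent.
    """
    offset = _NA_OFFSET[mode]
    out = []
    parents = [(ap.peak.mass, ap) for ap in annotated if ap.annotated]
    for ap in annotated:
        match = None
        for pmass, parent in parents:
            expected = pmass + offset
            if abs(ap.peak.mass - expected) <= tol.window_da(ap.peak.mass) and parent is not ap:
                match = (pmass, parent)
                break
        if match is None:
            out.append(ap)
            continue
        flags = set(ap.flags) | {"sodium_adduct"}
        assignments = ap.assignments
        if not assignments:
            flags.add("inherited_assignments")
            flags.discard("unannotated")
            assignments = match[1].assignments
        out.append(
            replace(ap, flags=frozenset(flags), assignments=assignments, adduct_parent_mass=match[0])
        )
    return out


# ---------------------------------------------------------------------------
# abundance aggregation
# ---------------------------------------------------------------------------


def fractional_abundances(
    annotated: Sequence[AnnotatedPeak],
    merge_oxidation: bool = True,
) -> list[GlycoformLibraryEntry]:
    """Glycoform fractional abundances across an annotated spectrum.

    Each glycoform receives sum over peaks of (relative peak intensity x
    hit score / 100).  Sodium-adduct satellites that merely inherited their
    parent's assignments are excluded from both the intensity total and the
    numerators (their signal duplicates the parent's glycoforms); a peak
    with assignments of its own always counts, even if it also sits in an
    adduct window.  Oxidation variants are merged into their parent
    glycoform by construction of the assignment keying.
    """
    if not annotated:
        raise ValueError("no annotated peaks")
    considered = [ap for ap in annotated if "inherited_assignments" not in ap.flags]
    total_intensity = sum(ap.peak.intensity for ap in considered)
    if total_intensity <= 0:
        raise ValueError("total spectrum intensity is zero")
    acc: dict[str, list] = {}
    for ap in considered:
        weight = ap.peak.intensity / total_intensity
        for a in ap.assignments:
            rec = acc.get(a.label)
            share = weight * a.hit_score / 100.0
            if rec is None:
                acc[a.label] = [a, share]
            else:
                rec[1] += share
    entries = [
        GlycoformLibraryEntry(
            label=a.label,
            species=a.species,
            composition=a.composition,
            abundance=share,
            site_names=a.site_names,
        )
        for a, share in acc.values()
    ]
    entries.sort(key=lambda e: (-e.abundance, e.label))
    return entries


def abundance_coverage(
    entries: Sequence[GlycoformLibraryEntry], threshold: float
) -> tuple[int, float]:
    """Count entries above an abundance threshold and their share of the total."""
    total = sum(e.abundance for e in entries)
    above = [e for e in entries if e.abundance > threshold]
    share = sum(e.abundance for e in above) / total if total > 0 else 0.0
    return len(above), share
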