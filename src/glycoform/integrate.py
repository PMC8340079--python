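"""Stepwise integration of structural levels: subunit -> noncovalent dimer.

Annotated subunit spectra are condensed into whole-chain glycoform libraries
(oxidation-merged fractional abundances, truncated at a fractional-abundance
cutoff, 0.3% by default).  The dimer spectrum is then annotated over a
two-pseudo-site space — one pseudo-site per chain, whose "species" are whole
subunit glycoforms — using average masses, since native spectra of the
complex are not isotopically resolved.  Noncovalent association adds no
mass: the theoretical dimer mass is the exact sum of the chain masses.

Subunit spectra are commonly measured reduced and carbamidomethylated while
the dimer is native (disulfide-bonded, unalkylated), so chain glycoform
entries carry their glycan composition independently of backbone chemistry
and are re-based onto the native backbone before dimer annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

from .annotate import (
    AnnotatedPeak,
    CompositionBounds,
    GlycoformAssignment,
    Peak,
    Tolerance,
    decompose_mass,
    fractional_abundances,
    nearest_composition,
    _flag_sodium_adducts,
    _rank_key,
)
from .chem import (
    GlycanComposition,
    MassMode,
    ProteinBackbone,
    backbone_mass,
    composition_mass,
)
from .library import (
    GlycoformLibraryEntry,
    LibraryError,
    TruncationResult,
    truncate_by_cutoff,
)

__all__ = [
    "BackboneChemistry",
    "ChainLibrary",
    "DimerLibrary",
    "build_subunit_library",
    "convert_backbone_context",
    "annotate_dimer",
]

# the combinatorial space grows as the product of per-chain entry counts;
# warn (do not fail) above this per-chain size
LIBRARY_SIZE_WARNING = 120


@dataclass(frozen=True)
class BackboneChemistry:
    """Cysteine chemistry of an analysis context."""

    carbamidomethylated: bool
    disulfides: int

    @classmethod
    def reduced_alkylated(cls) -> "BackboneChemistry":
        return cls(carbamidomethylated=True, disulfides=0)

    @classmethod
    def native(cls, disulfides: int) -> "BackboneChemistry":
        return cls(carbamidomethylated=False, disulfides=disulfides)


def convert_backbone_context(
    backbone: ProteinBackbone, to_chemistry: BackboneChemistry
) -> ProteinBackbone:
    """Re-base a backbone onto a different cysteine chemistry.

    Glycan compositions are untouched; only the fixed-modification state
    (carbamidomethylation, disulfide count) changes.
    """
    if not isinstance(to_chemistry, BackboneChemistry):
        raise TypeError("undefined target chemistry")
    return replace(
        backbone,
        carbamidomethyl_cys=to_chemistry.carbamidomethylated,
        disulfides=to_chemistry.disulfides,
    )


def build_subunit_library(
    annotated: Sequence[AnnotatedPeak], cutoff: float = 0.003
) -> TruncationResult:
    """Condense an annotated subunit spectrum into a glycoform library.

    Fractional abundances (oxidation variants merged) are truncated at
    ``cutoff``; the result reports the retained count and the retained share
    of total abundance (coverage is always relative to the pre-truncation
    total).
    """
    if not annotated:
        raise LibraryError("cannot build a library from an empty annotation")
    entries = fractional_abundances(annotated)
    result = truncate_by_cutoff(entries, cutoff)
    if result.retained_count == 0:
        raise LibraryError(
            f"cutoff {cutoff} removed every glycoform "
            f"(max abundance {max(e.abundance for e in entries):.3g}); empty library"
        )
    return result


@dataclass(frozen=True)
class ChainLibrary:
    """One dimer pseudo-site: a chain backbone plus its glycoform entries."""

    backbone: ProteinBackbone
    entries: tuple[GlycoformLibraryEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise LibraryError(f"chain {self.backbone.identifier!r} has no glycoforms")
        if len(self.entries) > LIBRARY_SIZE_WARNING:
            warnings.warn(
                f"chain {self.backbone.identifier!r} holds {len(self.entries)} "
                f"glycoforms (> {LIBRARY_SIZE_WARNING}); the pair search space "
                "may be large",
                stacklevel=2,
            )

    def normalized_weights(self) -> tuple[float, ...]:
        total = sum(e.abundance for e in self.entries)
        if total <= 0:
            raise LibraryError("chain glycoform abundances sum to zero")
        return tuple(e.abundance / total for e in self.entries)


@dataclass(frozen=True)
class DimerLibrary:
    """Two ordered pseudo-sites (chain A, chain B) for dimer annotation."""

    chain_a: ChainLibrary
    chain_b: ChainLibrary


def _check_native(backbone: ProteinBackbone) -> None:
    if backbone.carbamidomethyl_cys:
        raise ValueError(
            f"backbone {backbone.identifier!r} is carbamidomethylated; "
            "dimer annotation requires native chemistry "
            "(use convert_backbone_context)"
        )


def annotate_dimer(
    peaks: Sequence[Peak],
    dimer_lib: DimerLibrary,
    tol: Tolerance = Tolerance(3.0, "Da"),
    mode: MassMode = MassMode.average,
    detect_adducts: bool = True,
    report_near_miss: bool = True,
) -> list[AnnotatedPeak]:
    """Annotate a native dimer spectrum as combinations of chain glycoforms.

    The raw score of a chain pair is the product of the two chains'
    (renormalized) glycoform abundances; hit scores normalize to 100% per
    peak exactly as at subunit level.
    """
    mode = MassMode(mode)
    _check_native(dimer_lib.chain_a.backbone)
    _check_native(dimer_lib.chain_b.backbone)

    bb_a = backbone_mass(dimer_lib.chain_a.backbone, mode)
    bb_b = backbone_mass(dimer_lib.chain_b.backbone, mode)
    base = bb_a + bb_b  # noncovalent association: exact sum, no mass change

    w_a = dimer_lib.chain_a.normalized_weights()
    w_b = dimer_lib.chain_b.normalized_weights()
    entries_a = dimer_lib.chain_a.entries
    entries_b = dimer_lib.chain_b.entries

    # group chain-B glycoforms by composition for O(1) pair completion
    by_comp_b: dict[GlycanComposition, list[int]] = {}
    for j, e in enumerate(entries_b):
        by_comp_b.setdefault(e.composition, []).append(j)

    # bounds wide enough for the richest pair; completeness over the pair
    # space is guaranteed by the exact-composition matching below
    max_bounds = CompositionBounds(
        hex=max(e.composition.hex for e in entries_a) + max(e.composition.hex for e in entries_b),
        hexnac=max(e.composition.hexnac for e in entries_a)
        + max(e.composition.hexnac for e in entries_b),
        fuc=max(e.composition.fuc for e in entries_a) + max(e.composition.fuc for e in entries_b),
        neu5ac=max(e.composition.neu5ac for e in entries_a)
        + max(e.composition.neu5ac for e in entries_b),
    )

    site_names = (
        dimer_lib.chain_a.backbone.identifier,
        dimer_lib.chain_b.backbone.identifier,
    )

    annotated: list[AnnotatedPeak] = []
    for peak in peaks:
        residual = peak.mass - base
        hits = decompose_mass(
            residual, tol, bounds=max_bounds, mode=mode, reference_mass=peak.mass
        )
        assignments: list[GlycoformAssignment] = []
        total_raw = 0.0
        for hit in hits:
            target = hit.composition
            for i, ea in enumerate(entries_a):
                ca = ea.composition
                if (
                    ca.hex > target.hex
                    or ca.hexnac > target.hexnac
                    or ca.fuc > target.fuc
                    or ca.neu5ac > target.neu5ac
                ):
                    continue
                need = GlycanComposition(
                    target.hex - ca.hex,
                    target.hexnac - ca.hexnac,
                    target.fuc - ca.fuc,
                    target.neu5ac - ca.neu5ac,
                )
                for j in by_comp_b.get(need, ()):
                    eb = entries_b[j]
                    raw = w_a[i] * w_b[j]
                    theo = base + composition_mass(target, mode)
                    err = tol.error(peak.mass, theo)
                    assignments.append(
                        GlycoformAssignment(
                            species=ea.species + eb.species,
                            site_names=site_names,
                            composition=target,
                            theoretical_mass=theo,
                            error=err,
                            raw_score=raw,
                            hit_score=0.0,
                            chain_labels=(ea.label, eb.label),
                        )
                    )
                    total_raw += raw
        if total_raw > 0:
            assignments = [
                replace(a, hit_score=100.0 * a.raw_score / total_raw) for a in assignments
            ]
        assignments.sort(key=_rank_key)
        flags: set[str] = set()
        near = None
        if not assignments:
            flags.add("unannotated")
            if report_near_miss:
                window = max(2.0, 10.0 * tol.window_da(peak.mass))
                near = nearest_composition(
                    residual, bounds=max_bounds, mode=mode, search_window_da=window
                )
        annotated.append(
            AnnotatedPeak(
                peak=peak,
                assignments=tuple(assignments),
                flags=frozenset(flags),
                near_miss=near,
            )
        )

    if detect_adducts:
        annotated = _flag_sodium_adducts(annotated, tol, mode)
    return annotated


def chain_pair_label(assignment: GlycoformAssignment) -> tuple[str, str]:
    """(chain A glycoform, chain B glycoform) labels of a dimer assignment."""
    if not assignment.chain_labels:
        raise ValueError("assignment does not originate from annotate_dimer")
    return tuple(assignment.chain_labels)
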