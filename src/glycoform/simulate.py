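"""Ground-truthed synthetic libraries and deconvoluted peak lists.

The generator emulates the statistical structure the annotation engine
assumes in real deconvoluted spectra of heavily glycosylated proteins:

* per-site categorical glycan abundances (Dirichlet-distributed), with
  N-site occupancy below 100% encoded through the ``unmodified`` species;
* neutral-mass peaks whose intensity is the summed abundance of every
  glycoform falling inside a resolution window (isobaric collapse — MS
  cannot resolve isobaric proteoforms);
* Gaussian mass error (ppm or Da), multiplicative log-normal intensity
  noise, optional sodium-adduct satellites (+22 Da) and the −1 Da
  deconvolution artifact of sulfur-rich proteins.

Everything is reproducible under a seed, and a :class:`SimulationTruth`
records the noiseless contributor set of every peak so recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotate import MINUS1_DA, Peak
from .chem import (
    MassMode,
    ProteinBackbone,
    backbone_mass,
    composition_mass,
    modification_mass,
)
from .library import GlycoformLibraryEntry, SiteGlycanLibrary, library_from_mapping
from .metrics import (
    UndefinedMetricError,
    degree_of_core_fucosylation,
    degree_of_sialylation,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_library",
    "enumerate_glycoforms",
    "simulate_spectrum",
    "simulate_dimer",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic scenario.

    ``sites`` maps each site label to its candidate glycan pool (nomenclature
    strings); ``occupancy`` gives per-N-site occupied fractions (sites absent
    from the mapping are fully occupied).  The resolution window defaults to
    0.1 Da, appropriate for isotopically resolved subunit spectra; dimer-like
    simulations use 3 Da (set explicitly).
    """

    seed: int = 0
    sites: Mapping[str, Sequence[str]] = field(default_factory=dict)
    occupancy: Mapping[str, float] = field(default_factory=dict)
    dirichlet_concentration: float = 1.0
    mass_error_sigma: float = 0.0
    mass_error_unit: str = "ppm"  # ppm | Da
    resolution_window_da: float = 0.1
    adduct_probability: float = 0.0
    adduct_intensity_ratio: float = 0.2
    artifact_probability: float = 0.0
    intensity_noise_sigma: float = 0.0  # sigma of ln(intensity) perturbation
    abundance_floor: float = 1e-6
    mass_mode: MassMode = MassMode.monoisotopic

    def __post_init__(self) -> None:
        for p in (self.adduct_probability, self.artifact_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mass_error_sigma < 0 or self.intensity_noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.resolution_window_da <= 0:
            raise ValueError("resolution window must be positive")
        for site, occ in self.occupancy.items():
            if not 0.0 < occ <= 1.0:
                raise ValueError(f"occupancy {occ} at {site!r} outside (0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class SimulationTruth:
    """Noiseless record of what the generator put into a spectrum.

    ``contributors[i]`` lists (glycoform entry, true abundance) for
    ``peaks[i]``; contributions sum to the peak's noiseless intensity.
    ``peak_kinds[i]`` is ``signal`` or ``adduct``; ``artifact[i]`` marks the
    −1 Da shift.  ``entries`` is the full enumerated glycoform population
    and ``library`` the site library it came from (when applicable).
    """

    entries: tuple[GlycoformLibraryEntry, ...]
    contributors: tuple[tuple[tuple[GlycoformLibraryEntry, float], ...], ...]
    peak_kinds: tuple[str, ...]
    artifact: tuple[bool, ...]
    library: SiteGlycanLibrary | None
    sialylation: float | None
    core_fucosylation: float | None

    def top_contributor(self, i: int) -> GlycoformLibraryEntry:
        return max(self.contributors[i], key=lambda t: t[1])[0]


def simulate_library(config: SimulationConfig) -> SiteGlycanLibrary:
    """Draw a site-specific quantitative glycan library from the config prior."""
    if not config.sites:
        raise ValueError("empty glycan pool: config.sites has no sites")
    rng = config.rng()
    mapping: dict[str, list[tuple[str, float]]] = {}
    for site, pool in config.sites.items():
        pool = list(pool)
        if not pool:
            raise ValueError(f"empty glycan pool at site {site!r}")
        weights = rng.dirichlet(np.full(len(pool), config.dirichlet_concentration))
        entries = list(zip(pool, (float(w) for w in weights)))
        occ = config.occupancy.get(site)
        if occ is not None and occ < 1.0:
            entries = [(g, w * occ) for g, w in entries]
            entries.append(("unmodified", 1.0 - occ))
        mapping[site] = entries
    return library_from_mapping(mapping, mass_mode=config.mass_mode)


def enumerate_glycoforms(
    lib: SiteGlycanLibrary, floor: float = 1e-6
) -> list[GlycoformLibraryEntry]:
    """All site-species combinations with product abundance >= ``floor``."""
    sites = list(lib.sites.items())
    # suffix maxima let us prune branches that cannot reach the floor
    suffix_max = [1.0] * (len(sites) + 1)
    for i in range(len(sites) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] * max(w for _, w in sites[i][1])
    site_names = tuple(name for name, _ in sites)
    out: list[GlycoformLibraryEntry] = []

    def recurse(i: int, chosen: list, weight: float):
        if weight * suffix_max[i] < floor:
            return
        if i == len(sites):
            comp = chosen[0].composition
            for sp in chosen[1:]:
                comp = comp + sp.composition
            out.append(
                GlycoformLibraryEntry(
                    label="/".join(sp.name for sp in chosen),
                    species=tuple(chosen),
                    composition=comp,
                    abundance=weight,
                    site_names=site_names,
                )
            )
            return
        for sp, w in sites[i][1]:
            chosen.append(sp)
            recurse(i + 1, chosen, weight * w)
            chosen.pop()

    recurse(0, [], 1.0)
    out.sort(key=lambda e: (-e.abundance, e.label))
    return out


def _entry_mass(entry: GlycoformLibraryEntry, backbone_da: float, mode: MassMode) -> float:
    m = backbone_da + composition_mass(entry.composition, mode)
    if entry.deamidation_count:
        m += entry.deamidation_count * modification_mass("deamidation", mode)
    return m


def _assemble(
    entries: Sequence[GlycoformLibraryEntry],
    masses: Sequence[float],
    config: SimulationConfig,
    rng: np.random.Generator,
    mode: MassMode,
    library: SiteGlycanLibrary | None,
) -> tuple[list[Peak], SimulationTruth]:
    order = sorted(range(len(entries)), key=lambda i: masses[i])
    # greedy isobaric collapse: a cluster absorbs entries within the window
    # of its first (lowest-mass) member
    clusters: list[list[int]] = []
    for i in order:
        if clusters and masses[i] - masses[clusters[-1][0]] <= config.resolution_window_da:
            clusters[-1].append(i)
        else:
            clusters.append([i])

    peaks: list[Peak] = []
    contributors: list[tuple[tuple[GlycoformLibraryEntry, float], ...]] = []
    kinds: list[str] = []
    artifact: list[bool] = []
    for cluster in clusters:
        total = sum(entries[i].abundance for i in cluster)
        mass = sum(masses[i] * entries[i].abundance for i in cluster) / total
        contrib = tuple((entries[i], entries[i].abundance) for i in cluster)

        obs_mass = mass
        is_artifact = bool(rng.random() < config.artifact_probability)
        if is_artifact:
            obs_mass -= MINUS1_DA
        if config.mass_error_sigma > 0:
            sigma_da = (
                config.mass_error_sigma * mass / 1e6
                if config.mass_error_unit == "ppm"
                else config.mass_error_sigma
            )
            obs_mass += rng.normal(0.0, sigma_da)
        intensity = total
        if config.intensity_noise_sigma > 0:
            intensity *= float(np.exp(rng.normal(0.0, config.intensity_noise_sigma)))
        peaks.append(Peak(mass=obs_mass, intensity=intensity))
        contributors.append(contrib)
        kinds.append("signal")
        artifact.append(is_artifact)

        if rng.random() < config.adduct_probability:
            offset = modification_mass("sodium_adduct", mode)
            peaks.append(
                Peak(mass=obs_mass + offset, intensity=intensity * config.adduct_intensity_ratio)
            )
            contributors.append(contrib)
            kinds.append("adduct")
            artifact.append(is_artifact)

    try:
        sia = degree_of_sialylation(entries)
    except UndefinedMetricError:
        sia = None
    try:
        fuc = degree_of_core_fucosylation(entries)
    except UndefinedMetricError:
        fuc = None

    truth = SimulationTruth(
        entries=tuple(entries),
        contributors=tuple(contributors),
        peak_kinds=tuple(kinds),
        artifact=tuple(artifact),
        library=library,
        sialylation=sia,
        core_fucosylation=fuc,
    )
    return peaks, truth


def simulate_spectrum(
    lib: SiteGlycanLibrary,
    backbone: ProteinBackbone,
    config: SimulationConfig,
) -> tuple[list[Peak], SimulationTruth]:
    """Generate a deconvoluted subunit spectrum plus its ground truth."""
    mode = MassMode(lib.mass_mode)
    if mode is not MassMode(config.mass_mode):
        raise ValueError("mass-mode mismatch between library and config")
    rng = config.rng()
    entries = enumerate_glycoforms(lib, floor=config.abundance_floor)
    bb = backbone_mass(backbone, mode)
    masses = [_entry_mass(e, bb, mode) for e in entries]
    return _assemble(entries, masses, config, rng, mode, lib)


def simulate_dimer(
    entries_a: Sequence[GlycoformLibraryEntry],
    entries_b: Sequence[GlycoformLibraryEntry],
    backbone_a: ProteinBackbone,
    backbone_b: ProteinBackbone,
    config: SimulationConfig,
) -> tuple[list[Peak], SimulationTruth]:
    """Generate a native dimer spectrum from two chain glycoform libraries.

    Chain pairing is independent: the abundance of a pair is the product of
    the (renormalized) chain glycoform abundances.
    """
    mode = MassMode(config.mass_mode)
    rng = config.rng()
    bb_a = backbone_mass(backbone_a, mode)
    bb_b = backbone_mass(backbone_b, mode)
    tot_a = sum(e.abundance for e in entries_a)
    tot_b = sum(e.abundance for e in entries_b)
    pairs: list[GlycoformLibraryEntry] = []
    for ea in entries_a:
        wa = ea.abundance / tot_a
        for eb in entries_b:
            w = wa * eb.abundance / tot_b
            if w < config.abundance_floor:
                continue
            pairs.append(
                GlycoformLibraryEntry(
                    label=f"{ea.label} // {eb.label}",
                    species=ea.species + eb.species,
                    composition=ea.composition + eb.composition,
                    abundance=w,
                    site_names=(backbone_a.identifier, backbone_b.identifier),
                )
            )
    masses = [_entry_mass(p, bb_a + bb_b, mode) for p in pairs]
    return _assemble(pairs, masses, config, rng, mode, None)
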