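"""Reference synthetic scenarios mirroring a gonadotropin-like glycoprotein.

These frozen study conditions are shared by the test suite and the
reproduction script: a heterodimeric, heavily glycosylated hormone with two
N-sites per chain, three O-regions of capacity two on the beta chain,
biantennary sialylated complex N-glycans (some core-fucosylated, plus minor
tri-antennary and high-mannose species) and mono-/disialylated core-1
O-glycans.  One N-site is partially occupied (62.6%), matching the
occupancy observed for the beta chain's first sequon.

The per-site abundance profiles are drawn from a flat Dirichlet prior under
a caller-supplied seed; the pools, occupancy, abundance floor (1e-6) and
resolution windows (0.1 Da for isotopically resolved subunit spectra, 3 Da
for unresolved native dimer spectra) are fixed.
"""

from __future__ import annotations

from .chem import MassMode, ProteinBackbone
from .integrate import BackboneChemistry, convert_backbone_context
from .io import read_fasta
from .library import GlycoformLibraryEntry, SiteGlycanLibrary
from .simulate import SimulationConfig, enumerate_glycoforms, simulate_library

__all__ = [
    "N_GLYCAN_POOL",
    "O_GLYCAN_POOL",
    "hcg_backbones",
    "subunit_scenario",
    "dimer_scenario",
]

N_GLYCAN_POOL = (
    "A1G1",
    "A2",
    "A2G1",
    "A2G2",
    "A2S1G1",
    "A2S2",
    "A2G2F",
    "A2S1G1F",
    "A2S2F",
    "A3S2G1",
    "A3S3",
    "M5",
)

# O-regions hold up to two core-1 units; "unmodified" encodes empty regions
O_GLYCAN_POOL = (
    "unmodified",
    "core-1",
    "core-1 + S",
    "core-1 + 2 S",
    "2 x core-1",
    "2 x core-1 + S",
    "2 x core-1 + 2 S",
    "2 x core-1 + 3 S",
    "2 x core-1 + 4 S",
)

N13_OCCUPANCY = 0.626


def hcg_backbones() -> dict[str, str]:
    """The bundled mature alpha (92 aa) and beta (145 aa) chain sequences."""
    from . import bundled_path

    return read_fasta(str(bundled_path("hcg.fasta")))


def subunit_scenario(
    seed: int, mass_error_sigma_ppm: float = 0.0
) -> tuple[SimulationConfig, SiteGlycanLibrary, ProteinBackbone]:
    """Beta-like subunit: 2 N-sites + 3 O-regions, reduced/alkylated chain."""
    config = SimulationConfig(
        seed=seed,
        sites={
            "N13": N_GLYCAN_POOL,
            "N30": N_GLYCAN_POOL,
            "O115-122": O_GLYCAN_POOL,
            "O123-133": O_GLYCAN_POOL,
            "O134-145": O_GLYCAN_POOL,
        },
        occupancy={"N13": N13_OCCUPANCY},
        mass_error_sigma=mass_error_sigma_ppm,
        mass_error_unit="ppm",
        resolution_window_da=0.1,
        abundance_floor=1e-6,
        mass_mode=MassMode.monoisotopic,
    )
    library = simulate_library(config)
    backbone = ProteinBackbone(
        identifier="hCG_beta",
        sequence=hcg_backbones()["hCG_beta"],
        carbamidomethyl_cys=True,
    )
    return config, library, backbone


def dimer_scenario(
    seed: int,
) -> tuple[
    SimulationConfig,
    list[GlycoformLibraryEntry],
    list[GlycoformLibraryEntry],
    ProteinBackbone,
    ProteinBackbone,
]:
    """Native heterodimer with <= 60 glycoforms per chain, average masses.

    Chain glycoform lists are enumerated from per-chain site libraries
    (alpha: two N-sites; beta: one N-site and one O-region, echoing the
    dominant heterogeneity axes) drawn under chain-specific subseeds.
    """
    sequences = hcg_backbones()
    cfg_a = SimulationConfig(
        seed=seed * 2 + 1,
        sites={"N52": N_GLYCAN_POOL[:8], "N78": N_GLYCAN_POOL[2:9]},
        mass_mode=MassMode.average,
    )
    cfg_b = SimulationConfig(
        seed=seed * 2 + 2,
        sites={"N13": N_GLYCAN_POOL[:7], "O115-145": O_GLYCAN_POOL[:7]},
        occupancy={"N13": N13_OCCUPANCY},
        mass_mode=MassMode.average,
    )
    entries_a = enumerate_glycoforms(simulate_library(cfg_a), floor=0.0)
    entries_b = enumerate_glycoforms(simulate_library(cfg_b), floor=0.0)
    backbone_a = convert_backbone_context(
        ProteinBackbone("hCG_alpha", sequences["hCG_alpha"]), BackboneChemistry.native(5)
    )
    backbone_b = convert_backbone_context(
        ProteinBackbone("hCG_beta", sequences["hCG_beta"]), BackboneChemistry.native(6)
    )
    config = SimulationConfig(
        seed=seed,
        mass_mode=MassMode.average,
        resolution_window_da=3.0,
        abundance_floor=1e-6,
    )
    return config, entries_a, entries_b, backbone_a, backbone_b
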