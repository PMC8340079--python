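"""Multi-level glycoform annotation for heavily glycosylated protein complexes.

Annotates deconvoluted neutral-mass spectra of glycoprotein subunits and
their noncovalent complexes with ranked, probability-scored glycoform
assignments, propagates site-specific quantitative glycan libraries upward
(glycopeptide -> subunit -> dimer) and computes abundance-weighted
glycosylation quality attributes for batch comparison.
"""

__version__ = "0.1.0"

from .chem import (  # noqa: F401
    GlycanComposition,
    GlycanSpecies,
    MassMode,
    ProteinBackbone,
    backbone_mass,
    composition_mass,
    parse_glycan_name,
    ppm_error,
)
from .digest import find_sequons, max_glycans_at_level, tryptic_digest  # noqa: F401
from .library import (  # noqa: F401
    GlycoformLibraryEntry,
    SiteGlycanLibrary,
    count_candidate_glycoforms,
    deNglycosylate_library,
    desialylate_library,
    library_from_mapping,
    load_library,
    truncate_by_cutoff,
)
from .annotate import (  # noqa: F401
    AnnotatedPeak,
    CompositionBounds,
    Peak,
    Tolerance,
    abundance_coverage,
    annotate_spectrum,
    assign_sites,
    decompose_mass,
    fractional_abundances,
)
from .integrate import (  # noqa: F401
    BackboneChemistry,
    ChainLibrary,
    DimerLibrary,
    annotate_dimer,
    build_subunit_library,
    convert_backbone_context,
)
from .metrics import (  # noqa: F401
    CqaResult,
    compare_batches,
    degree_of_core_fucosylation,
    degree_of_sialylation,
)
from .simulate import (  # noqa: F401
    SimulationConfig,
    SimulationTruth,
    enumerate_glycoforms,
    simulate_dimer,
    simulate_library,
    simulate_spectrum,
)


def bundled_path(name: str):
    """Path to a data file bundled with the package (sequences, mass tables)."""
    from importlib import resources

    return resources.files("glycoform.data").joinpath(name)
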