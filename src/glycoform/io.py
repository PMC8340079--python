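"""File formats, configuration and provenance.

Interchange formats are deliberately plain: FASTA for sequences (read via
Biopython), tab-separated text with declared headers for site libraries,
peak lists, glycoform libraries and annotation reports, YAML for pipeline
configuration and JSON for the provenance block every CLI run writes.
Neutral-mass peak lists (not m/z) are the interchange unit: annotation
operates downstream of charge-state deconvolution.  Residue coordinates are
1-based inclusive throughout.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .annotate import AnnotatedPeak, Peak, Tolerance
from .chem import GlycanSpecies, MassMode, parse_glycan_name
from .digest import GlycosylationSite
from .library import GlycoformLibraryEntry
from .metrics import CqaResult

__all__ = [
    "PipelineConfig",
    "read_fasta",
    "read_sites",
    "read_peaks",
    "write_peaks",
    "write_annotation_report",
    "read_glycoform_library",
    "write_glycoform_library",
    "write_cqa_report",
    "write_provenance",
    "load_config",
]

REPORT_COLUMNS = [
    "peak_mass",
    "peak_intensity",
    "rank",
    "glycoform",
    "composition",
    "theoretical_mass",
    "error",
    "hit_score_percent",
    "flags",
]


@dataclass
class PipelineConfig:
    """Run settings; defaults reproduce the published analysis settings.

    20 ppm tolerance for isotopically resolved subunit spectra, +/-3 Da for
    the unresolved native dimer, 0.3% fractional-abundance cutoff for chain
    glycoform libraries and 0.04% as the coverage-reporting threshold.
    """

    sequences: str = ""
    library: str = ""
    peaks: str = ""
    mass_mode: str = "monoisotopic"
    tolerance_value: float = 20.0
    tolerance_unit: str = "ppm"
    dimer_tolerance_da: float = 3.0
    library_cutoff: float = 0.003
    coverage_threshold: float = 0.0004
    carbamidomethylated: bool = True
    disulfides: int = 0
    max_oxidations: int = 0
    detect_adducts: bool = True
    rescue_minus1da: bool = False
    seed: int = 0

    def tolerance(self) -> Tolerance:
        return Tolerance(self.tolerance_value, self.tolerance_unit)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = PipelineConfig().__dict__
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**data)


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_sites(path) -> list[GlycosylationSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        GlycosylationSite(
            subunit=row.subunit,
            kind=row.kind,
            start=int(row.start),
            end=int(row.end),
            capacity=int(row.capacity),
        )
        for row in df.itertuples()
    ]


def read_peaks(path) -> list[Peak]:
    df = pd.read_csv(path, sep="\t")
    missing = {"mass_da", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"peak list lacks column(s) {sorted(missing)}")
    return [Peak(mass=float(m), intensity=float(i)) for m, i in zip(df["mass_da"], df["intensity"])]


def write_peaks(peaks: Sequence[Peak], path) -> None:
    df = pd.DataFrame({"mass_da": [p.mass for p in peaks], "intensity": [p.intensity for p in peaks]})
    df.to_csv(path, sep="\t", index=False)


def annotation_report_frame(annotated: Sequence[AnnotatedPeak]) -> pd.DataFrame:
    """One row per (peak, rank); unannotated peaks keep a rank-0 stub row."""
    rows = []
    for ap in annotated:
        flags = ";".join(sorted(ap.flags))
        if not ap.assignments:
            near = ""
            if ap.near_miss is not None:
                near = f"nearest {ap.near_miss.composition} ({ap.near_miss.error:+.3f})"
            rows.append(
                dict(
                    peak_mass=ap.peak.mass,
                    peak_intensity=ap.peak.intensity,
                    rank=0,
                    glycoform=near,
                    composition="",
                    theoretical_mass=float("nan"),
                    error=float("nan"),
                    hit_score_percent=0.0,
                    flags=flags,
                )
            )
            continue
        for rank, a in enumerate(ap.assignments, start=1):
            row = dict(
                peak_mass=ap.peak.mass,
                peak_intensity=ap.peak.intensity,
                rank=rank,
                glycoform=a.label,
                composition=str(a.composition),
                theoretical_mass=a.theoretical_mass,
                error=a.error,
                hit_score_percent=a.hit_score,
                flags=flags,
            )
            if a.chain_labels:
                row["chain_a_glycoform"], row["chain_b_glycoform"] = a.chain_labels
            rows.append(row)
    df = pd.DataFrame(rows)
    ordered = REPORT_COLUMNS + [c for c in df.columns if c not in REPORT_COLUMNS]
    return df[ordered]


def write_annotation_report(annotated: Sequence[AnnotatedPeak], path) -> None:
    annotation_report_frame(annotated).to_csv(path, sep="\t", index=False)


def write_glycoform_library(entries: Sequence[GlycoformLibraryEntry], path) -> None:
    df = pd.DataFrame(
        {
            "glycoform": [e.label for e in entries],
            "composition": [str(e.composition) for e in entries],
            "fractional_abundance": [e.abundance for e in entries],
            "sites": ["/".join(e.site_names) for e in entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _parse_label_species(label: str) -> tuple[GlycanSpecies, ...]:
    from .chem import deamidated_unmodified

    species = []
    for token in label.split("/"):
        token = token.strip()
        if token == "unmodified (deamidated)":
            species.append(deamidated_unmodified())
        else:
            species.append(parse_glycan_name(token))
    return tuple(species)


def read_glycoform_library(path) -> list[GlycoformLibraryEntry]:
    """Read a glycoform library, reconstructing species from the labels."""
    df = pd.read_csv(path, sep="\t")
    entries = []
    for row in df.itertuples():
        species = _parse_label_species(row.glycoform)
        comp = species[0].composition
        for sp in species[1:]:
            comp = comp + sp.composition
        sites = tuple(str(row.sites).split("/")) if "sites" in df.columns else ()
        entries.append(
            GlycoformLibraryEntry(
                label=row.glycoform,
                species=species,
                composition=comp,
                abundance=float(row.fractional_abundance),
                site_names=sites,
            )
        )
    return entries


def write_cqa_report(results: Sequence[CqaResult], path) -> None:
    pd.DataFrame(
        {
            "level": [r.level for r in results],
            "target": [r.target for r in results],
            "sialylation": [r.sialylation for r in results],
            "core_fucosylation": [r.core_fucosylation for r in results],
            "weight_used": [r.weight_used for r in results],
        }
    ).to_csv(path, sep="\t", index=False)


def write_provenance(path, config: dict, seed: int | None = None) -> None:
    """Machine-readable record sufficient to re-run a deterministic stage."""
    block = {
        "tool": "glycoform",
        "version": __version__,
        "mass_tables": "monosaccharides.tsv/modifications.tsv v1 (IUPAC 2013 averages)",
        "seed": seed,
        "config": config,
        "python": sys.version.split()[0],
    }
    Path(path).write_text(json.dumps(block, indent=2, sort_keys=True, default=str) + "\n")
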