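"""Mass tables, glycan nomenclature and mass arithmetic.

Everything downstream (library transforms, the two-stage annotation search,
quality metrics) is built on three primitives defined here:

* :class:`GlycanComposition` — integer monosaccharide counts over the
  four-unit alphabet Hex / HexNAc / Fuc (dHex) / Neu5Ac.  Mass arithmetic is
  strictly additive over residue (dehydrated) masses.
* :class:`GlycanSpecies` — a named glycan (complex/hybrid/high-mannose
  N-glycan or mucin-type core-1 O-glycan) with the structural attributes the
  quality metrics need: antenna count, core-fucose flag, number of O-glycan
  cores.
* :class:`ProteinBackbone` — an amino-acid chain with its fixed-modification
  chemistry (carbamidomethylation, disulfides), the reference mass from which
  glycan residual masses are computed.

Two mass modes are supported throughout: monoisotopic (isotopically resolved
subunit spectra) and average, the latter computed from IUPAC 2013 standard
atomic weights (unresolved native spectra of the intact complex).  Residue
masses are loaded from delimited-text tables bundled with the package so the
alphabet can be extended without touching code.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from functools import lru_cache

from pyteomics import mass as _pt_mass

__all__ = [
    "MassMode",
    "GlycanComposition",
    "GlycanClass",
    "GlycanSpecies",
    "ProteinBackbone",
    "GlycanNameError",
    "monosaccharide_mass",
    "modification_mass",
    "parse_glycan_name",
    "canonical_name",
    "composition_mass",
    "backbone_mass",
    "ppm_error",
    "EMPTY_COMPOSITION",
    "UNMODIFIED",
]


class MassMode(str, enum.Enum):
    """Mass scale used for a computation context."""

    monoisotopic = "monoisotopic"
    average = "average"


# ---------------------------------------------------------------------------
# residue mass tables (data, not code)
# ---------------------------------------------------------------------------

# IUPAC 2013 standard atomic weights (conventional values) and monoisotopic
# masses, used to derive amino-acid residue masses from their elemental
# compositions (compositions from pyteomics).
_ATOMIC = {
    MassMode.monoisotopic: {
        "H": 1.00782503207,
        "C": 12.0,
        "N": 14.0030740048,
        "O": 15.9949146196,
        "S": 31.97207100,
    },
    MassMode.average: {
        "H": 1.008,
        "C": 12.011,
        "N": 14.007,
        "O": 15.999,
        "S": 32.06,
    },
}


def _load_table(name: str) -> dict[str, dict[MassMode, float]]:
    text = resources.files("glycoform.data").joinpath(name).read_text()
    rows = [ln.split("\t") for ln in text.strip().splitlines()]
    header = rows[0]
    assert header == ["name", "monoisotopic", "average"], header
    return {
        r[0]: {MassMode.monoisotopic: float(r[1]), MassMode.average: float(r[2])}
        for r in rows[1:]
    }


_MONOSACCHARIDES = _load_table("monosaccharides.tsv")
_MODIFICATIONS = _load_table("modifications.tsv")

MONOSACCHARIDE_NAMES = ("Hex", "HexNAc", "Fuc", "Neu5Ac")


def monosaccharide_mass(name: str, mode: MassMode) -> float:
    """Residue (dehydrated) mass of a monosaccharide unit in Da."""
    return _MONOSACCHARIDES[name][MassMode(mode)]


def modification_mass(name: str, mode: MassMode) -> float:
    """Mass of a backbone modification in Da (negative for disulfide)."""
    return _MODIFICATIONS[name][MassMode(mode)]


@lru_cache(maxsize=None)
def _aa_residue_mass(aa: str, mode: MassMode) -> float:
    comp = _pt_mass.std_aa_comp[aa]
    table = _ATOMIC[mode]
    return sum(n * table[el] for el, n in comp.items())


# ---------------------------------------------------------------------------
# compositions
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Non-negative monosaccharide counts; the unit of mass arithmetic."""

    hex: int = 0
    hexnac: int = 0
    fuc: int = 0
    neu5ac: int = 0

    def __post_init__(self) -> None:
        for unit in (self.hex, self.hexnac, self.fuc, self.neu5ac):
            if unit < 0:
                raise ValueError(f"negative monosaccharide count in {self}")

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hex + other.hex,
            self.hexnac + other.hexnac,
            self.fuc + other.fuc,
            self.neu5ac + other.neu5ac,
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "Hex": self.hex,
            "HexNAc": self.hexnac,
            "Fuc": self.fuc,
            "Neu5Ac": self.neu5ac,
        }

    def __str__(self) -> str:
        parts = [f"{k}{v}" for k, v in self.as_dict().items() if v]
        return " ".join(parts) if parts else "none"


EMPTY_COMPOSITION = GlycanComposition()


def composition_mass(comp: GlycanComposition, mode: MassMode) -> float:
    """Additive residue mass of a composition: sum(count_i * residue_mass_i)."""
    mode = MassMode(mode)
    return (
        comp.hex * _MONOSACCHARIDES["Hex"][mode]
        + comp.hexnac * _MONOSACCHARIDES["HexNAc"][mode]
        + comp.fuc * _MONOSACCHARIDES["Fuc"][mode]
        + comp.neu5ac * _MONOSACCHARIDES["Neu5Ac"][mode]
    )


# ---------------------------------------------------------------------------
# glycan nomenclature
# ---------------------------------------------------------------------------


class GlycanClass(str, enum.Enum):
    N = "N"
    O = "O"
    none = "none"


class GlycanNameError(ValueError):
    """Raised when a glycan name does not conform to the grammar."""


@dataclass(frozen=True)
class GlycanSpecies:
    """A named glycan with the structural attributes metrics rely on.

    Structural fields (``mannose``, ``gal``, ``sia``, ``lacn``, ``cores``)
    retain the parse so that in-silico enzymatic rewrites (desialylation,
    de-N-glycosylation) can regenerate a canonical name; ``composition`` is
    always derivable from them.  ``deamidated`` marks the Asn->Asp scar a
    PNGase F-released N-site leaves on the backbone (+0.984 Da) and is
    carried by the species so that occupancy bookkeeping survives the
    transform.
    """

    name: str
    glycan_class: GlycanClass
    composition: GlycanComposition
    antennae: int = 0
    core_fucose: bool = False
    cores: int = 0  # number of core-1 O-glycan units
    mannose: int = 0
    gal: int = 0
    sia: int = 0
    lacn: int = 0
    deamidated: bool = False

    @property
    def neu5ac_count(self) -> int:
        return self.composition.neu5ac

    @property
    def is_unmodified(self) -> bool:
        return self.glycan_class is GlycanClass.none

    def __str__(self) -> str:
        return self.name


UNMODIFIED = GlycanSpecies(
    name="unmodified",
    glycan_class=GlycanClass.none,
    composition=EMPTY_COMPOSITION,
)

# Grammar (names as used for biantennary complex glycans, high-mannose and
# mucin-type core-1 O-glycans):
#   complex    A<a>[S<s>][G<g>][F]         HexNAc 2+a, Hex 3+s+g, Neu5Ac s,
#                                          Fuc 1 if F
#   high-man   M<n>                        Hex n, HexNAc 2
#   hybrid     M<n>-A<a>[S<s>][G<g>][F]    Hex n+s+g, HexNAc 2+a
#   O-glycan   [k x ]core-1[ + j S]        k x (HexNAc1 Hex1) + j Neu5Ac
#   suffixes   "+ LacN<k>" adds k x (Hex1 HexNAc1); "+ <j> S" adds j Neu5Ac
#   reserved   "unmodified" (empty composition, class none)
_COMPLEX_RE = re.compile(r"^(?:M(?P<man>\d+)-)?A(?P<a>\d+)(?:S(?P<s>\d+))?(?:G(?P<g>\d+))?(?P<f>F)?$")
_HIGHMAN_RE = re.compile(r"^M(?P<man>\d+)$")
_CORE1_RE = re.compile(r"^(?:(?P<k>\d+)\s*[x×]\s*)?core-1$", re.IGNORECASE)
_LACN_RE = re.compile(r"^LacN(?P<k>\d+)?$", re.IGNORECASE)
_SIA_RE = re.compile(r"^(?:(?P<j>\d+)\s*[x×]?\s*)?S$")


def _build_n_species(man: int, a: int, s: int, g: int, fuc: bool, lacn: int, extra_sia: int) -> GlycanSpecies:
    sia = s + extra_sia
    comp = GlycanComposition(
        hex=man + s + g + lacn,
        hexnac=2 + a + lacn,
        fuc=1 if fuc else 0,
        neu5ac=sia,
    )
    sp = GlycanSpecies(
        name="",
        glycan_class=GlycanClass.N,
        composition=comp,
        antennae=a,
        core_fucose=fuc,
        mannose=man,
        gal=g,
        sia=sia,
        lacn=lacn,
    )
    return replace(sp, name=canonical_name(sp))


def _build_o_species(cores: int, sia: int) -> GlycanSpecies:
    comp = GlycanComposition(hex=cores, hexnac=cores, neu5ac=sia)
    sp = GlycanSpecies(
        name="",
        glycan_class=GlycanClass.O,
        composition=comp,
        cores=cores,
        sia=sia,
    )
    return replace(sp, name=canonical_name(sp))


def canonical_name(sp: GlycanSpecies) -> str:
    """Regenerate the canonical nomenclature string for a species."""
    if sp.glycan_class is GlycanClass.none:
        return "unmodified"
    if sp.glycan_class is GlycanClass.O:
        base = "core-1" if sp.cores == 1 else f"{sp.cores} x core-1"
        if sp.sia:
            base += " + S" if sp.sia == 1 else f" + {sp.sia} S"
        return base
    # N-glycans.  For complex/hybrid species sialic acids are shown in the
    # S-antenna count; gal-terminated antennae in G.
    if sp.antennae == 0:
        return f"M{sp.mannose}"
    stem = "" if sp.mannose == 3 else f"M{sp.mannose}-"
    name = f"{stem}A{sp.antennae}"
    if sp.sia:
        name += f"S{sp.sia}"
    if sp.gal:
        name += f"G{sp.gal}"
    if sp.core_fucose:
        name += "F"
    if sp.lacn:
        name += f" + LacN{sp.lacn}"
    return name


def parse_glycan_name(name: str) -> GlycanSpecies:
    """Parse a glycan nomenclature string into a :class:`GlycanSpecies`.

    Raises :class:`GlycanNameError` naming the offending token when the name
    does not conform to the grammar.
    """
    raw = name.strip()
    if not raw:
        raise GlycanNameError("empty glycan name")
    if raw.lower() == "unmodified":
        return UNMODIFIED

    parts = [p.strip() for p in raw.split("+")]
    base, suffixes = parts[0], parts[1:]

    lacn = 0
    extra_sia = 0
    for tok in suffixes:
        m = _LACN_RE.match(tok)
        if m:
            lacn += int(m.group("k") or 1)
            continue
        m = _SIA_RE.match(tok)
        if m:
            extra_sia += int(m.group("j") or 1)
            continue
        raise GlycanNameError(f"unrecognized suffix token {tok!r} in {name!r}")

    m = _CORE1_RE.match(base)
    if m:
        if lacn:
            raise GlycanNameError(f"LacN suffix not allowed on O-glycan {name!r}")
        return _build_o_species(cores=int(m.group("k") or 1), sia=extra_sia)

    m = _COMPLEX_RE.match(base)
    if m:
        man = int(m.group("man") or 3)
        return _build_n_species(
            man=man,
            a=int(m.group("a")),
            s=int(m.group("s") or 0),
            g=int(m.group("g") or 0),
            fuc=m.group("f") is not None,
            lacn=lacn,
            extra_sia=extra_sia,
        )

    m = _HIGHMAN_RE.match(base)
    if m:
        if extra_sia or lacn:
            raise GlycanNameError(f"suffixes not allowed on high-mannose {name!r}")
        man = int(m.group("man"))
        comp = GlycanComposition(hex=man, hexnac=2)
        sp = GlycanSpecies(
            name="",
            glycan_class=GlycanClass.N,
            composition=comp,
            mannose=man,
        )
        return replace(sp, name=canonical_name(sp))

    raise GlycanNameError(f"unparseable glycan name token {base!r} in {name!r}")


def desialylate_species(sp: GlycanSpecies) -> GlycanSpecies:
    """In-silico sialidase: strip every Neu5Ac, regenerating the name.

    Sialylated antennae of complex N-glycans become galactose-terminated
    (A2S2 -> A2G2); O-glycans lose their "+ n S" suffix.
    """
    if sp.composition.neu5ac == 0:
        return sp
    if sp.glycan_class is GlycanClass.O:
        return _build_o_species(cores=sp.cores, sia=0)
    return _build_n_species(
        man=sp.mannose,
        a=sp.antennae,
        s=0,
        g=sp.gal + sp.sia,
        fuc=sp.core_fucose,
        lacn=sp.lacn,
        extra_sia=0,
    )


def deamidated_unmodified() -> GlycanSpecies:
    """The species left behind by PNGase F at a formerly occupied N-site."""
    return replace(UNMODIFIED, name="unmodified (deamidated)", deamidated=True)


# ---------------------------------------------------------------------------
# protein backbones
# ---------------------------------------------------------------------------

_CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinBackbone:
    """An amino-acid chain plus its fixed-modification chemistry.

    ``carbamidomethyl_cys`` applies carbamidomethylation to every cysteine
    not engaged in a disulfide; disulfide bonds each remove two hydrogens.
    ``max_oxidations`` bounds the variable Met/Trp oxidation count considered
    during annotation (the variants are merged again when abundances are
    computed).
    """

    identifier: str
    sequence: str
    carbamidomethyl_cys: bool = False
    disulfides: int = 0
    max_oxidations: int = 0

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _CANONICAL_AA
        if bad:
            raise ValueError(
                f"unknown residue letter(s) {sorted(bad)} in backbone {self.identifier!r}"
            )
        n_cys = self.sequence.count("C")
        if self.disulfides > n_cys // 2:
            raise ValueError(
                f"{self.disulfides} disulfides impossible with {n_cys} Cys"
            )
        if self.disulfides < 0 or self.max_oxidations < 0:
            raise ValueError("negative modification count")

    @property
    def n_cys(self) -> int:
        return self.sequence.count("C")

    @property
    def n_carbamidomethyl(self) -> int:
        # CAM and disulfide formation on the same Cys are mutually exclusive
        return (self.n_cys - 2 * self.disulfides) if self.carbamidomethyl_cys else 0


def backbone_mass(backbone: ProteinBackbone, mode: MassMode) -> float:
    """Neutral chain mass: residues + one water + fixed modifications."""
    mode = MassMode(mode)
    total = sum(_aa_residue_mass(aa, mode) for aa in backbone.sequence)
    total += _ATOMIC[mode]["H"] * 2 + _ATOMIC[mode]["O"]  # termini
    total += backbone.n_carbamidomethyl * _MODIFICATIONS["carbamidomethyl"][mode]
    total += backbone.disulfides * _MODIFICATIONS["disulfide"][mode]
    return total


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical
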