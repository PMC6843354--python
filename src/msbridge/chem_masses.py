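"""Monoisotopic mass bookkeeping for peptides, oligonucleotides and bridges.

Every mass in the pipeline is a neutral monoisotopic mass in daltons,
computed by summing an explicit elemental composition against a single
element table. Cross-linker bridges (NHS esters in light d0 and heavy d4
form) and platinum adducts (bifunctional diammine bridge, monofunctional
chloro-diammine "dangling" adduct) are expressed the same way, so that
conjugate masses are additive by construction.

Platinum needs an explicit monoisotopic reference: its isotope envelope is
broad and deconvolution software reports the most-abundant-isotope peak.
The default is 195Pt (most abundant); 194Pt can be selected per adduct
definition.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence, Union

import yaml

# ---------------------------------------------------------------------------
# Element table

#: Monoisotopic masses (Da). "D" is deuterium (2H).
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "D": 2.01410177785,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Cl": 34.96885268,
    "Pt": 194.9647911,      # 195Pt, most abundant isotope
    "Pt194": 193.9626803,   # 194Pt alternative reference
}

MASS_H2O = 2 * ELEMENT_MASSES["H"] + ELEMENT_MASSES["O"]
MASS_HPO3 = ELEMENT_MASSES["H"] + ELEMENT_MASSES["P"] + 3 * ELEMENT_MASSES["O"]
#: heavy-light shift of one H->D substitution
MASS_H_TO_D = ELEMENT_MASSES["D"] - ELEMENT_MASSES["H"]

Formula = Mapping[str, int]


def formula_mass(formula: Formula) -> float:
    """Sum a {element: count} composition against the element table."""
    total = 0.0
    for element, count in formula.items():
        try:
            total += ELEMENT_MASSES[element] * count
        except KeyError:
            raise ValueError(f"unknown element symbol {element!r}") from None
    return total


def _merge(*formulas: Formula) -> dict[str, int]:
    out: Counter[str] = Counter()
    for f in formulas:
        out.update(f)
    return dict(out)


# ---------------------------------------------------------------------------
# Residue compositions

#: Amino-acid residue compositions (peptide-bond residues, i.e. minus water).
AA_COMPOSITIONS: dict[str, Formula] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

#: 2'-deoxyribonucleoside compositions (free nucleoside, both OH termini).
NUCLEOSIDE_COMPOSITIONS: dict[str, Formula] = {
    "A": {"C": 10, "H": 13, "N": 5, "O": 3},
    "C": {"C": 9, "H": 13, "N": 3, "O": 4},
    "G": {"C": 10, "H": 13, "N": 5, "O": 4},
    "T": {"C": 10, "H": 14, "N": 2, "O": 5},
}

AA_MASSES: dict[str, float] = {a: formula_mass(f) for a, f in AA_COMPOSITIONS.items()}
NUCLEOSIDE_MASSES: dict[str, float] = {
    b: formula_mass(f) for b, f in NUCLEOSIDE_COMPOSITIONS.items()
}


# ---------------------------------------------------------------------------
# Species

@dataclass(frozen=True)
class PeptideSpecies:
    """A proteolytic peptide in construct numbering (1-based, inclusive)."""

    sequence: str
    start: int = 1
    end: int = 0
    n_term: str = "H"        # free amine: +H on the backbone N
    c_term: str = "OH"       # free acid: +OH on the backbone C
    modifications: tuple[float, ...] = ()   # fixed mass deltas (Da)
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for ch in self.sequence:
            if ch not in AA_COMPOSITIONS:
                raise ValueError(f"unknown amino-acid symbol {ch!r}")
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"positions {self.start}-{self.end} inconsistent with "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OligoSpecies:
    """A DNA fragment with explicit 5'/3' termini ("OH" or "phosphate")."""

    sequence: str
    strand: str = "forward"
    start: int = 1
    end: int = 0
    five_prime: str = "OH"
    three_prime: str = "OH"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("oligonucleotide sequence must be non-empty")
        for ch in self.sequence:
            if ch not in NUCLEOSIDE_COMPOSITIONS:
                raise ValueError(f"non-ACGT symbol {ch!r} in DNA sequence")
        for term, label in ((self.five_prime, "5'"), (self.three_prime, "3'")):
            if term not in ("OH", "phosphate"):
                raise ValueError(f"{label} terminus must be 'OH' or 'phosphate', got {term!r}")
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("positions inconsistent with sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# Linker / adduct definitions

@dataclass(frozen=True)
class CrosslinkerDef:
    """A homobifunctional NHS-ester cross-linker with optional heavy form.

    ``light_bridge`` / ``heavy_bridge`` are the compositions *added* to the
    sum of component masses by a bridging cross-link (the diacid spacer
    minus two waters). A mono-link (one end hydrolyzed) adds bridge + H2O.
    ``span`` and ``span_tol`` (Å) describe the heteroatom distance the
    bridge can cover, side-chain allowance included.
    """

    name: str
    light_bridge: Formula
    heavy_bridge: Formula | None
    reactive_residues: frozenset[str] = frozenset({"K", "S"})
    reacts_n_term: bool = True
    span: float = 0.0
    span_tol: float = 0.0

    @property
    def light_mass(self) -> float:
        return formula_mass(self.light_bridge)

    @property
    def heavy_mass(self) -> float:
        if self.heavy_bridge is None:
            raise ValueError(f"cross-linker {self.name} has no heavy isotope form")
        return formula_mass(self.heavy_bridge)

    def bridge_mass(self, form: str = "light") -> float:
        if form == "light":
            return self.light_mass
        if form == "heavy":
            return self.heavy_mass
        raise ValueError(f"isotope form must be 'light' or 'heavy', got {form!r}")

    def monolink_mass(self, form: str = "light") -> float:
        """Mass delta of a hydrolyzed single-ended attachment."""
        return self.bridge_mass(form) + MASS_H2O


@dataclass(frozen=True)
class PtAdductDef:
    """Transplatin adduct chemistry.

    The bifunctional bridge Pt(NH3)2 has displaced both chlorides and links
    a protein nucleophile (Cys/Met/His/Thr side chains by default) to a DNA
    base (guanine N7 preferred). The monofunctional adduct Pt(NH3)2Cl keeps
    one chloride and decorates a single component. Coordination is modelled
    as adding the full adduct formula with no proton loss from the targets.
    """

    name: str = "transplatin"
    protein_reactive: frozenset[str] = frozenset({"C", "M", "H", "T"})
    reacts_protein_termini: bool = False
    dna_reactive: frozenset[str] = frozenset({"G"})
    pt_isotope: str = "Pt"   # "Pt" (195) or "Pt194"
    span: float = 5.0
    span_tol: float = 2.0

    @property
    def bifunctional_mass(self) -> float:
        """Pt(NH3)2 bridge delta."""
        return formula_mass({self.pt_isotope: 1, "N": 2, "H": 6})

    @property
    def monofunctional_mass(self) -> float:
        """Pt(NH3)2Cl dangling-adduct delta."""
        return formula_mass({self.pt_isotope: 1, "N": 2, "H": 6, "Cl": 1})


# ---------------------------------------------------------------------------
# Mass computation

_TERMINI_MASS = {
    "H": ELEMENT_MASSES["H"],
    "OH": ELEMENT_MASSES["O"] + ELEMENT_MASSES["H"],
}


def peptide_mass(p: PeptideSpecies) -> float:
    """Neutral monoisotopic mass of a peptide.

    Residue masses plus the terminal groups (free amine + free acid sum to
    one water) plus any fixed modification deltas.
    """
    total = sum(AA_MASSES[a] for a in p.sequence)
    total += _TERMINI_MASS[p.n_term] + _TERMINI_MASS[p.c_term]
    total += sum(p.modifications)
    return total


def oligo_mass(o: OligoSpecies) -> float:
    """Neutral monoisotopic mass of a DNA oligonucleotide.

    Built from nucleoside compositions: each internal phosphodiester adds
    HPO3 and removes one water; each phosphate terminus adds HPO3.
    """
    n = len(o.sequence)
    total = sum(NUCLEOSIDE_MASSES[b] for b in o.sequence)
    total += (n - 1) * (MASS_HPO3 - MASS_H2O)
    if o.five_prime == "phosphate":
        total += MASS_HPO3
    if o.three_prime == "phosphate":
        total += MASS_HPO3
    return total


Component = Union[PeptideSpecies, OligoSpecies, float]


def _component_mass(c: Component) -> float:
    if isinstance(c, PeptideSpecies):
        return peptide_mass(c)
    if isinstance(c, OligoSpecies):
        return oligo_mass(c)
    return float(c)


def conjugate_mass(
    components: Sequence[Component],
    bridge: CrosslinkerDef | PtAdductDef,
    mode: str = "light",
) -> float:
    """Neutral mass of a cross-linked species: component sum + bridge delta.

    ``mode`` selects the bridge chemistry: for NHS esters, "light"/"heavy"
    (two components) or "mono-light"/"mono-heavy" (one component, hydrolyzed
    other end); for Pt adducts, "bifunctional" (1 or 2 components) or
    "monofunctional" (one component).
    """
    if not 1 <= len(components) <= 2:
        raise ValueError(f"a conjugate has 1 or 2 components, got {len(components)}")
    base = sum(_component_mass(c) for c in components)
    if isinstance(bridge, PtAdductDef):
        if mode == "bifunctional":
            delta = bridge.bifunctional_mass
        elif mode == "monofunctional":
            if len(components) != 1:
                raise ValueError("a monofunctional Pt adduct decorates one component")
            delta = bridge.monofunctional_mass
        else:
            raise ValueError(f"Pt adduct mode must be 'bifunctional' or 'monofunctional', got {mode!r}")
    else:
        if mode in ("light", "heavy"):
            delta = bridge.bridge_mass(mode)
        elif mode in ("mono-light", "mono-heavy"):
            if len(components) != 1:
                raise ValueError("a mono-link involves exactly one component")
            delta = bridge.monolink_mass(mode.removeprefix("mono-"))
        else:
            raise ValueError(f"unknown bridge mode {mode!r}")
    return base + delta


def doublet_delta(x: CrosslinkerDef) -> float:
    """Exact monoisotopic heavy-light bridge mass difference (≈4.0251 Da for d4)."""
    return x.heavy_mass - x.light_mass


# ---------------------------------------------------------------------------
# Built-in linker definitions

def _bridge_with_deuteration(formula: Formula, n_d: int) -> dict[str, int]:
    f = dict(formula)
    f["H"] = f.get("H", 0) - n_d
    f["D"] = f.get("D", 0) + n_d
    if f["H"] < 0:
        raise ValueError("not enough hydrogens to deuterate")
    return f

_DSG_BRIDGE = {"C": 5, "H": 4, "O": 2}     # glutaric acid - 2 H2O
_DSS_BRIDGE = {"C": 8, "H": 10, "O": 2}    # suberic acid - 2 H2O

DSG = CrosslinkerDef(
    name="DSG",
    light_bridge=_DSG_BRIDGE,
    heavy_bridge=_bridge_with_deuteration(_DSG_BRIDGE, 4),
    span=20.5,
    span_tol=3.0,
)

DSS = CrosslinkerDef(
    name="DSS",
    light_bridge=_DSS_BRIDGE,
    heavy_bridge=_bridge_with_deuteration(_DSS_BRIDGE, 4),
    span=24.2,
    span_tol=3.0,
)

TRANSPLATIN = PtAdductDef()

BUILTIN_LINKERS: dict[str, CrosslinkerDef] = {"DSG": DSG, "DSS": DSS}


def load_linker_config(path=None) -> tuple[dict[str, CrosslinkerDef], dict[str, PtAdductDef]]:
    """Load linker/adduct chemistry from a YAML config.

    Without a path, the packaged default definitions (DSG, DSS, transplatin)
    are loaded. Returns ({name: CrosslinkerDef}, {name: PtAdductDef}).
    """
    if path is None:
        text = resources.files("msbridge").joinpath("data/linkers.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    linkers: dict[str, CrosslinkerDef] = {}
    for entry in cfg.get("crosslinkers", []):
        heavy = entry.get("heavy_bridge")
        linkers[entry["name"]] = CrosslinkerDef(
            name=entry["name"],
            light_bridge=entry["light_bridge"],
            heavy_bridge=heavy,
            reactive_residues=frozenset(entry.get("reactive_residues", ["K", "S"])),
            reacts_n_term=entry.get("reacts_n_term", True),
            span=float(entry.get("span", 0.0)),
            span_tol=float(entry.get("span_tol", 0.0)),
        )
    adducts: dict[str, PtAdductDef] = {}
    for entry in cfg.get("pt_adducts", []):
        adducts[entry["name"]] = PtAdductDef(
            name=entry["name"],
            protein_reactive=frozenset(entry.get("protein_reactive", ["C", "M", "H", "T"])),
            reacts_protein_termini=entry.get("reacts_protein_termini", False),
            dna_reactive=frozenset(entry.get("dna_reactive", ["G"])),
            pt_isotope=entry.get("pt_isotope", "Pt"),
            span=float(entry.get("span", 5.0)),
            span_tol=float(entry.get("span_tol", 2.0)),
        )
    return linkers, adducts
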