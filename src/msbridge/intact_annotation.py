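"""Intact-mass annotation of platinum adduct ladders.

Deconvoluted neutral masses from intact ESI-MS of a platinated protein-DNA
sample are explained as a base species (protein, single strands, duplex,
or complex) carrying n bifunctional Pt(NH3)2 bridges and m monofunctional
Pt(NH3)2Cl dangling adducts. A native-versus-denatured comparison then
classifies complexes as covalently bridged (they survive denaturation) or
merely non-covalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chem_masses import PtAdductDef


@dataclass(frozen=True)
class SpeciesModel:
    """A candidate intact species and its allowed adduct counts."""

    name: str
    base_mass: float
    max_bifunctional: int = 5
    max_monofunctional: int = 5
    is_complex: bool = False
    components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.base_mass <= 0:
            raise ValueError(f"base mass of {self.name} must be positive")
        if self.max_bifunctional < 0 or self.max_monofunctional < 0:
            raise ValueError("max adduct counts must be non-negative")


@dataclass(frozen=True)
class IntactAssignment:
    observed_mass: float
    species: str
    n_bifunctional: int
    n_monofunctional: int
    theoretical_mass: float
    ppm_error: float


def annotate_intact(
    peaklist: pd.DataFrame,
    species: list[SpeciesModel],
    adducts: PtAdductDef,
    ppm_tol: float = 5.0,
) -> list[IntactAssignment]:
    """Assign (species, n, m) adduct combinations to each observed mass.

    Exhaustive over n <= max_bifunctional and m <= max_monofunctional per
    species; every combination within tolerance is retained, sorted by
    |ppm| (ties by species name, then n, m) — ambiguity is preserved.
    """
    if not species:
        raise ValueError("species list must be non-empty")
    if ppm_tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    d_bi = adducts.bifunctional_mass
    d_mono = adducts.monofunctional_mass
    out: list[IntactAssignment] = []
    for obs in peaklist["mass"]:
        if obs <= 0:
            raise ValueError(f"non-positive peak mass {obs}")
        hits = []
        for sp in species:
            for n in range(sp.max_bifunctional + 1):
                for m in range(sp.max_monofunctional + 1):
                    theo = sp.base_mass + n * d_bi + m * d_mono
                    ppm = (obs - theo) / theo * 1e6
                    if abs(ppm) <= ppm_tol:
                        hits.append(IntactAssignment(obs, sp.name, n, m, theo, ppm))
        hits.sort(key=lambda a: (abs(a.ppm_error), a.species, a.n_bifunctional, a.n_monofunctional))
        out.extend(hits)
    return out


def bridged_species_test(
    assignments_native: list[IntactAssignment],
    assignments_denatured: list[IntactAssignment],
    species: list[SpeciesModel],
) -> dict[str, str]:
    """Classify complex species as bridged / non-bridged / unclassified.

    A complex still observed under denaturing conditions must be held
    together by covalent bifunctional bridges. A complex seen only natively,
    whose components appear individually once denatured, carries no
    intermolecular bridge. A complex absent from both sets is unclassified.
    """
    native = {a.species for a in assignments_native}
    denatured = {a.species for a in assignments_denatured}
    verdict: dict[str, str] = {}
    for sp in species:
        if not sp.is_complex:
            continue
        if sp.name in denatured:
            verdict[sp.name] = "bridged"
        elif sp.name in native:
            components_freed = all(c in denatured for c in sp.components) if sp.components else False
            verdict[sp.name] = "non-bridged" if components_freed else "unclassified"
        else:
            verdict[sp.name] = "unclassified"
    return verdict


def assignment_table(assignments: list[IntactAssignment]) -> pd.DataFrame:
    """Annotation table with ladder-style labels (e.g. 'complex + 2 tPt + 1 tPt-Cl')."""
    rows = []
    for a in assignments:
        label = a.species
        if a.n_bifunctional:
            label += f" + {a.n_bifunctional} tPt"
        if a.n_monofunctional:
            label += f" + {a.n_monofunctional} tPt-Cl"
        rows.append(
            {
                "observed_mass": a.observed_mass,
                "label": label,
                "species": a.species,
                "n_tPt": a.n_bifunctional,
                "n_tPt_Cl": a.n_monofunctional,
                "theoretical_mass": round(a.theoretical_mass, 5),
                "ppm_error": round(a.ppm_error, 3),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["observed_mass", "label", "species", "n_tPt", "n_tPt_Cl",
                 "theoretical_mass", "ppm_error"],
    )
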