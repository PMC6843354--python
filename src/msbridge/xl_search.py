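"""Theoretical cross-link library construction and neutral-mass matching.

Deconvoluted neutral monoisotopic masses are explained against a library of
theoretical cross-linked species: peptide-peptide bridges (inter), loop
links within one peptide, hydrolyzed mono-links, and peptide-DNA
conjugates bridged by a bifunctional platinum adduct. Matching is
mass-only: the gas-phase chemistry of Pt conjugates gives no backbone
fragments, so residue-level localization is never claimed beyond what the
reactive-class rules allow, and ambiguity is preserved rather than
resolved by guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_masses import (
    CrosslinkerDef,
    OligoSpecies,
    PeptideSpecies,
    PtAdductDef,
    conjugate_mass,
)


@dataclass(frozen=True)
class LibraryConfig:
    """Which candidate classes to enumerate."""

    include_inter: bool = True
    include_loop: bool = True
    include_mono: bool = True
    isotope_forms: tuple[str, ...] = ("light", "heavy")
    protein_start: int = 1     # construct position of the protein N-terminus


def component_label(c: PeptideSpecies | OligoSpecies) -> str:
    if isinstance(c, OligoSpecies):
        return f"{c.strand}:{c.sequence}({c.start}-{c.end})"
    return f"{c.sequence}({c.start}-{c.end})"


@dataclass(frozen=True)
class CandidateConjugate:
    """A theoretical cross-linked species with its reactive-site inventory."""

    type: str                   # inter | loop | mono | peptide-DNA
    components: tuple[PeptideSpecies | OligoSpecies, ...]
    linker: str
    form: str                   # light|heavy|mono-light|mono-heavy|bifunctional
    mass: float
    sites: tuple[tuple[int, ...], ...]   # reactive positions per component (construct numbering)

    @property
    def key(self) -> tuple:
        return (self.type, tuple(component_label(c) for c in self.components),
                self.linker, self.form)

    def label(self) -> str:
        comps = "+".join(component_label(c) for c in self.components)
        return f"{self.type}:{comps}:{self.linker}/{self.form}"


def peptide_reactive_sites(
    p: PeptideSpecies,
    linker: CrosslinkerDef | PtAdductDef,
    protein_start: int = 1,
) -> tuple[int, ...]:
    """Construct positions in ``p`` reactive towards ``linker``.

    The protein N-terminal amino group counts as a site (position =
    ``protein_start``) only for the N-terminal peptide and only when the
    chemistry targets primary amines at the terminus.
    """
    if isinstance(linker, PtAdductDef):
        residues = linker.protein_reactive
        n_term_ok = linker.reacts_protein_termini
    else:
        residues = linker.reactive_residues
        n_term_ok = linker.reacts_n_term
    sites = [p.start + i for i, aa in enumerate(p.sequence) if aa in residues]
    if n_term_ok and p.start == protein_start and protein_start not in sites:
        sites.insert(0, protein_start)
    return tuple(sites)


def oligo_reactive_sites(o: OligoSpecies, adduct: PtAdductDef) -> tuple[int, ...]:
    """Parent-strand positions of bases reactive towards the Pt adduct."""
    return tuple(o.start + i for i, b in enumerate(o.sequence) if b in adduct.dna_reactive)


def _dedup(cands: list[CandidateConjugate]) -> list[CandidateConjugate]:
    seen: dict[tuple, CandidateConjugate] = {}
    for c in cands:
        seen.setdefault(c.key, c)
    out = list(seen.values())
    out.sort(key=lambda c: c.label())
    return out


def build_library(
    peptides: list[PeptideSpecies],
    oligos: list[OligoSpecies] | None = None,
    linkers: list[CrosslinkerDef] | None = None,
    ptadduct: PtAdductDef | None = None,
    cfg: LibraryConfig | None = None,
) -> list[CandidateConjugate]:
    """Enumerate every type-valid candidate whose components carry the
    reactive sites their chemistry requires; deduplicated and sorted."""
    cfg = cfg or LibraryConfig()
    oligos = oligos or []
    linkers = linkers or []
    cands: list[CandidateConjugate] = []

    for linker in linkers:
        reactive = [
            (p, peptide_reactive_sites(p, linker, cfg.protein_start)) for p in peptides
        ]
        reactive = [(p, s) for p, s in reactive if s]
        for form in cfg.isotope_forms:
            if form == "heavy" and linker.heavy_bridge is None:
                continue
            if cfg.include_inter:
                for i in range(len(reactive)):
                    for j in range(i + 1, len(reactive)):
                        (pa, sa), (pb, sb) = reactive[i], reactive[j]
                        comps = tuple(sorted((pa, pb), key=component_label))
                        sites = tuple(
                            s for _, s in sorted(
                                ((pa, sa), (pb, sb)), key=lambda t: component_label(t[0])
                            )
                        )
                        cands.append(CandidateConjugate(
                            "inter", comps, linker.name, form,
                            conjugate_mass(comps, linker, form), sites))
            if cfg.include_loop:
                for p, s in reactive:
                    if len(s) >= 2:
                        cands.append(CandidateConjugate(
                            "loop", (p,), linker.name, form,
                            conjugate_mass((p,), linker, form), (s,)))
            if cfg.include_mono:
                for p, s in reactive:
                    cands.append(CandidateConjugate(
                        "mono", (p,), linker.name, f"mono-{form}",
                        conjugate_mass((p,), linker, f"mono-{form}"), (s,)))

    if ptadduct is not None and oligos:
        for p in peptides:
            ps = peptide_reactive_sites(p, ptadduct, cfg.protein_start)
            if not ps:
                continue
            for o in oligos:
                os_ = oligo_reactive_sites(o, ptadduct)
                if not os_:
                    continue
                comps = (p, o)
                cands.append(CandidateConjugate(
                    "peptide-DNA", comps, ptadduct.name, "bifunctional",
                    conjugate_mass(comps, ptadduct, "bifunctional"), (ps, os_)))

    if not cands and (peptides or oligos):
        import warnings
        warnings.warn("no reactive sites found anywhere: empty candidate library")
    return _dedup(cands)


def constant_unit_library(
    peptides: list[PeptideSpecies],
    fixed_oligo: OligoSpecies,
    ptadduct: PtAdductDef,
    cfg: LibraryConfig | None = None,
) -> list[CandidateConjugate]:
    """Peptide-DNA candidates via the constant-unit shortcut.

    Instead of enumerating oligo fragments, a single designated
    oligonucleotide bridged by one platinum equivalent is treated as a
    constant mass unit appended to every peptide that carries a
    protein-reactive site.
    """
    cfg = cfg or LibraryConfig()
    cands = []
    os_ = oligo_reactive_sites(fixed_oligo, ptadduct)
    for p in peptides:
        ps = peptide_reactive_sites(p, ptadduct, cfg.protein_start)
        if not ps:
            continue
        comps = (p, fixed_oligo)
        cands.append(CandidateConjugate(
            "peptide-DNA", comps, ptadduct.name, "bifunctional",
            conjugate_mass(comps, ptadduct, "bifunctional"), (ps, os_)))
    return _dedup(cands)


@dataclass(frozen=True)
class Identification:
    """An observed mass with all library candidates within tolerance."""

    observed_mass: float
    intensity: float
    matches: tuple[CandidateConjugate, ...]   # ranked
    ppm_errors: tuple[float, ...]
    state: str = ""

    @property
    def best(self) -> CandidateConjugate:
        return self.matches[0]


def match_peaks(
    peaklist: pd.DataFrame,
    library: list[CandidateConjugate],
    ppm_tol: float = 5.0,
    state: str = "",
) -> tuple[list[Identification], pd.DataFrame]:
    """Match deconvoluted neutral masses against the candidate library.

    Returns (identifications, unmatched peaks). Candidates within tolerance
    of a peak are ranked by |ppm|, then fewer components, then lexicographic
    label — a deterministic order for reproducible reports.
    """
    if not library:
        raise ValueError("candidate library is empty")
    if ppm_tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    lib_sorted = sorted(library, key=lambda c: c.mass)
    masses = np.array([c.mass for c in lib_sorted])

    ids: list[Identification] = []
    unmatched = []
    has_intensity = "intensity" in peaklist.columns
    for _, row in peaklist.iterrows():
        obs = float(row["mass"])
        inten = float(row["intensity"]) if has_intensity else float("nan")
        tol = obs * ppm_tol * 1e-6
        lo = int(np.searchsorted(masses, obs - tol, side="left"))
        hi = int(np.searchsorted(masses, obs + tol, side="right"))
        hits = []
        for c in lib_sorted[lo:hi]:
            ppm = (obs - c.mass) / c.mass * 1e6
            if abs(ppm) <= ppm_tol:
                hits.append((c, ppm))
        if not hits:
            unmatched.append({"mass": obs, "intensity": inten})
            continue
        hits.sort(key=lambda t: (abs(t[1]), len(t[0].components), t[0].label()))
        ids.append(Identification(
            observed_mass=obs, intensity=inten,
            matches=tuple(c for c, _ in hits),
            ppm_errors=tuple(p for _, p in hits),
            state=state))
    return ids, pd.DataFrame(unmatched, columns=["mass", "intensity"])


@dataclass(frozen=True)
class LocalizationReport:
    """Residue-level confidence for one identified candidate."""

    status: str              # "localized" | "composition-only"
    sites: tuple[tuple[int, ...], ...]
    unambiguous: bool


def site_localization_report(identification: Identification) -> LocalizationReport:
    """Localization status of the top-ranked candidate.

    Pt-bridged conjugates dissociate around the metal in the gas phase and
    yield no backbone fragments, so they are reported composition-only.
    NHS-ester candidates are localized to their reactive-class residues,
    with every alternative site enumerated when a component holds several.
    """
    cand = identification.best
    if cand.form in ("bifunctional", "monofunctional"):
        return LocalizationReport("composition-only", cand.sites, unambiguous=False)
    unambiguous = all(len(s) == 1 for s in cand.sites)
    return LocalizationReport("localized", cand.sites, unambiguous=unambiguous)


def identification_table(ids: list[Identification]) -> pd.DataFrame:
    """Flat identification table: one row per (peak, candidate) pair."""
    rows = []
    for group_id, ident in enumerate(ids):
        for cand, ppm in zip(ident.matches, ident.ppm_errors):
            rows.append({
                "state": ident.state,
                "type": cand.type,
                "components": "+".join(component_label(c) for c in cand.components),
                "positions": ";".join(
                    ",".join(map(str, s)) for s in cand.sites),
                "linker": cand.linker,
                "form": cand.form,
                "theoretical_mass": round(cand.mass, 6),
                "observed_mass": ident.observed_mass,
                "ppm": round(ppm, 4),
                "ambiguity_group": group_id,
            })
    return pd.DataFrame(rows, columns=[
        "state", "type", "components", "positions", "linker", "form",
        "theoretical_mass", "observed_mass", "ppm", "ambiguity_group"])
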