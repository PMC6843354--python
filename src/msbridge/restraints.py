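"""Cross-link derived distance restraints and their validation on structures.

Each identified conjugate implies an upper bound on the separation of the
bridged residues: the linker span (side-chain allowance included) plus a
tolerance. Localized NHS-ester links give one residue pair; class-ambiguous
links and composition-only Pt conjugates expand into ambiguous groups that
are satisfied when any member pair is. Distances are measured between
Calpha atoms for protein residues and guanine N7 for DNA by default, on
single structures or per-model across ensembles, and distance sets can be
compared between structures by RMSD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product

import gemmi
import numpy as np
import pandas as pd

from .chem_masses import CrosslinkerDef, PtAdductDef
from .xl_search import Identification, component_label
from .chem_masses import OligoSpecies, PeptideSpecies

_AA3 = set("""ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO
SER THR TRP TYR VAL""".split())
_DNA3 = {"DA", "DC", "DG", "DT", "A", "C", "G", "T"}


@dataclass(frozen=True)
class RestraintEnd:
    """One endpoint of a restraint: chain, residue number, atom selector.

    ``atom=None`` resolves to Calpha for amino acids and N7 for nucleotides
    at measurement time.
    """

    chain: str
    residue: int
    atom: str | None = None


@dataclass(frozen=True)
class DistanceRestraint:
    """Upper-bound restraint: satisfied when d <= span + tolerance."""

    end_a: RestraintEnd
    end_b: RestraintEnd
    span: float
    tolerance: float
    linker: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.span <= 0:
            raise ValueError("restraint span must be positive")
        if self.tolerance < 0:
            raise ValueError("restraint tolerance must be non-negative")

    @property
    def upper_bound(self) -> float:
        return self.span + self.tolerance


@dataclass(frozen=True)
class RestraintGroup:
    """An ambiguous group: satisfied if any member restraint is."""

    members: tuple[DistanceRestraint, ...]
    linker: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("restraint group must have at least one member")


@dataclass(frozen=True)
class SatisfactionReport:
    restraint: DistanceRestraint
    measured: float | None        # None: not evaluable
    satisfied: bool | None
    violation: float              # Å beyond the upper bound (0 when satisfied)


@dataclass(frozen=True)
class GroupSatisfaction:
    group: RestraintGroup
    reports: tuple[SatisfactionReport, ...]
    min_distance: float | None
    satisfied: bool | None


# ---------------------------------------------------------------------------
# Restraint generation

def xl_to_restraints(
    ids: list[Identification],
    linkers: dict[str, CrosslinkerDef],
    ptadduct: PtAdductDef | None = None,
    protein_chain: str = "A",
    dna_chains: dict[str, str] | None = None,
) -> list[RestraintGroup]:
    """Expand identifications into (possibly ambiguous) restraint groups.

    Inter peptide-peptide links restrain every site combination across the
    two peptides; loop links every site pair within one; mono-links carry no
    distance information and are skipped. Pt peptide-DNA conjugates are
    composition-only, so they restrain all reactive residues of the peptide
    against all reactive bases of the oligonucleotide, as one group.
    ``dna_chains`` maps strand labels ("forward"/"reverse") to chain names.
    """
    dna_chains = dna_chains or {"forward": "B", "reverse": "C"}
    groups: list[RestraintGroup] = []
    for ident in ids:
        cand = ident.best
        if cand.type == "mono":
            continue
        if any(not s for s in cand.sites):
            raise ValueError(f"identification {cand.label()} has a component with no reactive site")
        if cand.type == "peptide-DNA":
            if ptadduct is None:
                raise ValueError("peptide-DNA identification requires a Pt adduct definition")
            pep_sites, oligo_sites = cand.sites
            oligo = cand.components[1]
            chain_b = dna_chains[getattr(oligo, "strand", "forward")]
            members = tuple(
                DistanceRestraint(
                    RestraintEnd(protein_chain, rp),
                    RestraintEnd(chain_b, rb),
                    span=ptadduct.span, tolerance=ptadduct.span_tol,
                    linker=ptadduct.name, source=cand.label())
                for rp, rb in product(pep_sites, oligo_sites))
        else:
            linker = linkers[cand.linker]
            if cand.type == "inter":
                site_pairs = [
                    (a, b) for a, b in product(cand.sites[0], cand.sites[1]) if a != b
                ]
            else:  # loop
                s = cand.sites[0]
                site_pairs = [(a, b) for i, a in enumerate(s) for b in s[i + 1:]]
            if not site_pairs:
                continue
            members = tuple(
                DistanceRestraint(
                    RestraintEnd(protein_chain, min(a, b)),
                    RestraintEnd(protein_chain, max(a, b)),
                    span=linker.span, tolerance=linker.span_tol,
                    linker=linker.name, source=cand.label())
                for a, b in site_pairs)
        groups.append(RestraintGroup(members=members, linker=cand.linker, source=cand.label()))
    return groups


def apply_numbering_offset(groups: list[RestraintGroup], offsets: dict[str, int]) -> list[RestraintGroup]:
    """Shift residue numbers per chain (structure = construct + offset)."""
    out = []
    for g in groups:
        members = tuple(
            replace(m,
                    end_a=replace(m.end_a, residue=m.end_a.residue + offsets.get(m.end_a.chain, 0)),
                    end_b=replace(m.end_b, residue=m.end_b.residue + offsets.get(m.end_b.chain, 0)))
            for m in g.members)
        out.append(RestraintGroup(members=members, linker=g.linker, source=g.source))
    return out


# ---------------------------------------------------------------------------
# Measurement

def read_structure(path) -> gemmi.Structure:
    """Read a PDB/mmCIF file, raising a descriptive error on failure."""
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as e:
        raise ValueError(f"malformed structure file {path}: {e}") from e
    if len(st) == 0:
        raise ValueError(f"structure file {path} contains no models")
    st.setup_entities()
    return st


def _default_atom(residue: gemmi.Residue) -> str:
    name = residue.name.strip().upper()
    if name in _DNA3:
        return "N7" if name in ("DG", "G") else "N1"
    return "CA"


def resolve_atom(model: gemmi.Model, end: RestraintEnd):
    """Find the endpoint atom in a model; None when unresolvable."""
    for chain in model:
        if chain.name != end.chain:
            continue
        for residue in chain:
            if residue.seqid.num != end.residue:
                continue
            atom_name = end.atom or _default_atom(residue)
            atom = residue.find_atom(atom_name, "*")
            return atom
    return None


def measure(model: gemmi.Model | gemmi.Structure, r: DistanceRestraint) -> SatisfactionReport:
    """Measure one restraint on a model; unresolvable endpoints are reported
    as not-evaluable, never skipped."""
    if isinstance(model, gemmi.Structure):
        model = model[0]
    a = resolve_atom(model, r.end_a)
    b = resolve_atom(model, r.end_b)
    if a is None or b is None:
        return SatisfactionReport(restraint=r, measured=None, satisfied=None, violation=0.0)
    d = a.pos.dist(b.pos)
    satisfied = d <= r.upper_bound
    return SatisfactionReport(
        restraint=r, measured=d, satisfied=satisfied,
        violation=0.0 if satisfied else d - r.upper_bound)


def measure_group(model: gemmi.Model | gemmi.Structure, g: RestraintGroup) -> GroupSatisfaction:
    """Group satisfaction: the group holds if any member pair does."""
    reports = tuple(measure(model, m) for m in g.members)
    distances = [rep.measured for rep in reports if rep.measured is not None]
    if not distances:
        return GroupSatisfaction(group=g, reports=reports, min_distance=None, satisfied=None)
    return GroupSatisfaction(
        group=g, reports=reports,
        min_distance=min(distances),
        satisfied=any(rep.satisfied for rep in reports if rep.satisfied is not None))


def measure_ensemble(structure: gemmi.Structure, groups: list[RestraintGroup]) -> pd.DataFrame:
    """Per-restraint-group satisfaction fraction across ensemble models."""
    rows = []
    for i, g in enumerate(groups):
        verdicts = [measure_group(model, g).satisfied for model in structure]
        evaluable = [v for v in verdicts if v is not None]
        rows.append({
            "group": i,
            "source": g.source,
            "linker": g.linker,
            "n_models": len(structure),
            "n_evaluable": len(evaluable),
            "satisfaction_fraction": (sum(evaluable) / len(evaluable)) if evaluable else float("nan"),
        })
    return pd.DataFrame(rows, columns=[
        "group", "source", "linker", "n_models", "n_evaluable", "satisfaction_fraction"])


def compare_distance_sets(
    struct_a: gemmi.Structure | gemmi.Model,
    struct_b: gemmi.Structure | gemmi.Model,
    pairs: list[tuple[RestraintEnd, RestraintEnd]],
) -> tuple[pd.DataFrame, float]:
    """Per-pair distance deltas between two structures and their RMSD.

    Pairs unresolvable in either structure are excluded from the RMSD and
    flagged in the table.
    """
    ma = struct_a[0] if isinstance(struct_a, gemmi.Structure) else struct_a
    mb = struct_b[0] if isinstance(struct_b, gemmi.Structure) else struct_b
    rows, deltas = [], []
    for ea, eb in pairs:
        aa, ab = resolve_atom(ma, ea), resolve_atom(ma, eb)
        ba, bb = resolve_atom(mb, ea), resolve_atom(mb, eb)
        if None in (aa, ab, ba, bb):
            rows.append({"end_a": f"{ea.chain}:{ea.residue}", "end_b": f"{eb.chain}:{eb.residue}",
                         "d_a": float("nan"), "d_b": float("nan"),
                         "delta": float("nan"), "evaluable": False})
            continue
        da = aa.pos.dist(ab.pos)
        db = ba.pos.dist(bb.pos)
        deltas.append(da - db)
        rows.append({"end_a": f"{ea.chain}:{ea.residue}", "end_b": f"{eb.chain}:{eb.residue}",
                     "d_a": da, "d_b": db, "delta": da - db, "evaluable": True})
    rmsd = float(np.sqrt(np.mean(np.square(deltas)))) if deltas else float("nan")
    return pd.DataFrame(rows, columns=["end_a", "end_b", "d_a", "d_b", "delta", "evaluable"]), rmsd


# ---------------------------------------------------------------------------
# Export / import

SUPPORTED_FORMATS = ("tsv", "cns", "haddock")


def export_restraints(groups: list[RestraintGroup], fmt: str = "tsv") -> str:
    """Serialize restraint groups; ordering is deterministic (input order,
    members as given), so repeated export is byte-identical."""
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; supported: {', '.join(SUPPORTED_FORMATS)}")
    lines: list[str] = []
    if fmt == "tsv":
        lines.append("group\tchain_a\tres_a\tatom_a\tchain_b\tres_b\tatom_b\tspan\ttol\tlinker\tsource")
        for gi, g in enumerate(groups):
            for m in g.members:
                lines.append("\t".join(map(str, [
                    gi, m.end_a.chain, m.end_a.residue, m.end_a.atom or "-",
                    m.end_b.chain, m.end_b.residue, m.end_b.atom or "-",
                    f"{m.span:g}", f"{m.tolerance:g}", m.linker or "-", m.source or "-"])))
    elif fmt == "cns":
        lines.append("! distance restraints (simulated-annealing assign records)")
        for g in groups:
            for m in g.members:
                lines.append(
                    f"assign (segid {m.end_a.chain} and resid {m.end_a.residue} and name "
                    f"{m.end_a.atom or 'CA'}) (segid {m.end_b.chain} and resid {m.end_b.residue} "
                    f"and name {m.end_b.atom or 'CA'}) {m.span:g} {m.tolerance:g} {m.tolerance:g}")
    else:  # haddock ambiguous blocks
        lines.append("! ambiguous distance restraints")
        for gi, g in enumerate(groups):
            lines.append(f"! group {gi} ({g.linker}) {len(g.members)} member(s)")
            for k, m in enumerate(g.members):
                sel = (f"(segid {m.end_a.chain} and resid {m.end_a.residue}) "
                       f"(segid {m.end_b.chain} and resid {m.end_b.residue}) "
                       f"{m.span:g} {m.tolerance:g} {m.tolerance:g}")
                lines.append(("assign " if k == 0 else "    or ") + sel)
    return "\n".join(lines) + "\n"


def parse_restraints_tsv(text: str) -> list[RestraintGroup]:
    """Inverse of ``export_restraints(..., "tsv")``."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    by_group: dict[int, list[DistanceRestraint]] = {}
    meta: dict[int, tuple[str, str]] = {}
    for ln in lines[1:]:
        (gi, ca, ra, aa, cb, rb, ab, span, tol, linker, source) = ln.split("\t")
        gi = int(gi)
        by_group.setdefault(gi, []).append(DistanceRestraint(
            RestraintEnd(ca, int(ra), None if aa == "-" else aa),
            RestraintEnd(cb, int(rb), None if ab == "-" else ab),
            span=float(span), tolerance=float(tol),
            linker="" if linker == "-" else linker,
            source="" if source == "-" else source))
        meta[gi] = ("" if linker == "-" else linker, "" if source == "-" else source)
    return [
        RestraintGroup(members=tuple(by_group[gi]), linker=meta[gi][0], source=meta[gi][1])
        for gi in sorted(by_group)
    ]
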