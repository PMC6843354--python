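"""Ground-truth scenario generation for end-to-end pipeline validation.

Real inputs to this pipeline are deconvoluted neutral mass lists, centroid
time courses, and 3D structures. This module fabricates all of them from a
known truth: a self-avoiding toy fold (plus an ideal B-form duplex),
cross-links planted only between reactive residues that are genuinely
within linker span on that fold, peak lists with Gaussian ppm noise and
far-off decoys, d0/d4 doublets drawn at configured mixing fractions, and
two-state HDX kinetics with per-residue protection factors. Every stage of
the analysis can then be scored against the planted truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import gemmi
import numpy as np
import pandas as pd

from .chem_masses import (
    CrosslinkerDef,
    DSG,
    DSS,
    OligoSpecies,
    PeptideSpecies,
    PtAdductDef,
    TRANSPLATIN,
    conjugate_mass,
    doublet_delta,
    peptide_mass,
)
from .digestion import DigestConfig, trypsin_digest
from .hdx_analysis import DEFAULT_TIMEPOINTS, UptakeRecord, exchangeable_positions
from .xl_search import CandidateConjugate, build_library, peptide_reactive_sites

#: the two response-element strands used as the default duplex
DEFAULT_FORWARD = "TTGGGTAAACAAG"
DEFAULT_REVERSE = "CTTGTTTACCCAA"

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ScenarioConfig:
    """All knobs of a synthetic scenario; same config + seed => same outputs."""

    seed: int = 0
    protein_sequence: str | None = None
    # defaults emulate the study construct: a 134-residue DNA-binding domain
    # numbered 74..207, with binding-protected residues 103-130
    protein_length: int = 134
    protein_start: int = 74         # construct number of the first residue
    forward_strand: str = DEFAULT_FORWARD
    reverse_strand: str = DEFAULT_REVERSE
    # fold geometry
    bond_length: float = 3.8
    excluded_radius: float = 3.9
    max_retries: int = 200
    # peak lists
    ppm_noise_sd: float = 1.0
    n_decoys: int = 200
    decoy_min_ppm: float = 50.0
    base_intensity: float = 1.0e5
    intensity_cv: float = 0.05      # lognormal multiplicative noise
    n_replicates: int = 3
    # doublet quantification truth
    mixing_fractions: tuple[float, ...] = (0.959, 0.728, 0.5)
    # HDX truth
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    k_int: float = 1.0              # intrinsic exchange rate (1/min)
    protection_free: float = 5.0
    protection_complex_factor: float = 100.0
    protected_region: tuple[int, int] = (103, 130)   # construct numbering
    hdx_noise_sd: float = 0.0       # Da on peptide centroids
    # digestion for planted conjugates
    max_missed_cleavages: int = 1


@dataclass
class GroundTruth:
    """What the generator planted, for scoring the pipeline against."""

    sequence: str
    protein_start: int
    coords: np.ndarray                       # (L, 3) Calpha positions
    conjugates: list[CandidateConjugate]
    site_pairs: list[tuple[int, int]]
    mixing_fractions: list[float]
    protection_free: np.ndarray
    protection_complex: np.ndarray


def _rng(cfg: ScenarioConfig, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((cfg.seed * 1000003 + salt) % (2**31))


def random_protein(cfg: ScenarioConfig) -> str:
    """Random sequence with guaranteed K/R content so trypsin has sites."""
    rng = _rng(cfg, salt=1)
    seq = list(rng.choice(list(_ALPHABET), size=cfg.protein_length))
    # a cleavage site roughly every 8 residues keeps peptides MS-sized
    for i in range(7, cfg.protein_length - 1, 8):
        seq[i] = "K" if (i // 8) % 2 == 0 else "R"
    return "".join(seq)


# ---------------------------------------------------------------------------
# Fold generation

def gen_fold(cfg: ScenarioConfig) -> np.ndarray:
    """Self-avoiding random chain of Calpha positions, 3.8 Å steps."""
    length = len(cfg.protein_sequence) if cfg.protein_sequence else cfg.protein_length
    if length < 3:
        raise ValueError("fold length must be at least 3")
    rng = _rng(cfg, salt=2)
    for _ in range(cfg.max_retries):
        coords = [np.zeros(3)]
        ok = True
        for _i in range(length - 1):
            placed = False
            for _try in range(cfg.max_retries):
                v = rng.normal(size=3)
                v *= cfg.bond_length / np.linalg.norm(v)
                cand = coords[-1] + v
                if len(coords) < 2 or np.min(
                    np.linalg.norm(np.asarray(coords[:-1]) - cand, axis=1)
                ) >= cfg.excluded_radius:
                    coords.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(coords)
    raise RuntimeError("self-avoiding fold generation failed; try a different seed")


def gen_duplex_coords(n_bp: int, rise: float = 3.4, twist_deg: float = 36.0,
                      radius: float = 9.0, origin: np.ndarray | None = None) -> np.ndarray:
    """Idealized B-form duplex: one reference point per base per strand.

    Returns an (n_bp, 2, 3) array (strand 0 = forward 5'->3', strand 1 =
    reverse, paired antiparallel), with 3.4 Å rise and 36° twist per step.
    """
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    out = np.zeros((n_bp, 2, 3))
    groove_offset = math.radians(140.0)
    for i in range(n_bp):
        theta = math.radians(twist_deg) * i
        z = rise * i
        out[i, 0] = origin + [radius * math.cos(theta), radius * math.sin(theta), z]
        out[i, 1] = origin + [radius * math.cos(theta + groove_offset),
                              radius * math.sin(theta + groove_offset), z]
    return out


def fold_to_structure(
    coords: np.ndarray,
    sequence: str,
    protein_start: int = 1,
    chain: str = "A",
    duplex: np.ndarray | None = None,
    forward: str = "",
    reverse: str = "",
) -> gemmi.Structure:
    """Build a gemmi Structure from synthetic coordinates.

    Protein residues carry a single Calpha; DNA residues carry their
    measurement reference atom (N7 for G, N1 otherwise). The result is a
    synthetic stand-in structure, sufficient for restraint measurement.
    """
    three = {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
        "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
        "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
        "Y": "TYR", "V": "VAL",
    }
    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)
    for i, (aa, xyz) in enumerate(zip(sequence, coords)):
        res = gemmi.Residue()
        res.name = three[aa]
        res.seqid = gemmi.SeqId(protein_start + i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    if duplex is not None:
        for strand_idx, (name, seq) in enumerate((("B", forward), ("C", reverse))):
            dch = gemmi.Chain(name)
            for i, base in enumerate(seq):
                # reverse strand runs antiparallel: base i pairs bp n-1-i
                bp = i if strand_idx == 0 else len(seq) - 1 - i
                res = gemmi.Residue()
                res.name = "D" + base
                res.seqid = gemmi.SeqId(i + 1, " ")
                atom = gemmi.Atom()
                atom.name = "N7" if base == "G" else "N1"
                atom.element = gemmi.Element("N")
                atom.pos = gemmi.Position(*duplex[bp, strand_idx])
                res.add_atom(atom)
                dch.add_residue(res)
            model.add_chain(dch)
    st.add_model(model)
    return st


# ---------------------------------------------------------------------------
# Cross-link planting

def plant_crosslinks(
    coords: np.ndarray,
    sequence: str,
    linkers: list[CrosslinkerDef],
    cfg: ScenarioConfig,
    n_per_linker: int = 10,
) -> tuple[list[CandidateConjugate], list[tuple[int, int]], list[float]]:
    """Plant inter-peptide cross-links between reactive residues within span.

    Site pairs are sampled (without replacement) from residue pairs that
    (a) belong to the linker's reactive classes, (b) sit in different
    0-missed-cleavage tryptic peptides, and (c) are within span + tolerance
    on the fold. Returns (candidates, site pairs, mixing fractions cycled
    from the config).
    """
    rng = _rng(cfg, salt=3)
    peptides0 = trypsin_digest(sequence, DigestConfig(max_missed_cleavages=0))
    # shift peptides to construct numbering
    peptides0 = [
        PeptideSpecies(p.sequence, p.start + cfg.protein_start - 1,
                       p.end + cfg.protein_start - 1)
        for p in peptides0
    ]

    def peptide_of(pos: int) -> PeptideSpecies:
        for p in peptides0:
            if p.start <= pos <= p.end:
                return p
        raise ValueError(f"position {pos} not covered by any tryptic peptide")

    conjugates: list[CandidateConjugate] = []
    pairs: list[tuple[int, int]] = []
    fractions: list[float] = []
    seen_keys: set[tuple] = set()
    k = 0
    for linker in linkers:
        site_positions: list[int] = []
        for p in peptides0:
            site_positions.extend(peptide_reactive_sites(p, linker, cfg.protein_start))
        eligible = []
        for ai in range(len(site_positions)):
            for bi in range(ai + 1, len(site_positions)):
                a, b = site_positions[ai], site_positions[bi]
                pa, pb = peptide_of(a), peptide_of(b)
                if pa is pb:
                    continue
                d = float(np.linalg.norm(
                    coords[a - cfg.protein_start] - coords[b - cfg.protein_start]))
                if d <= linker.span + linker.span_tol:
                    eligible.append((a, b, pa, pb))
        if not eligible:
            import warnings
            warnings.warn(f"no residue pair within span for {linker.name}; nothing planted")
            continue
        taken = 0
        for i in rng.permutation(len(eligible)):
            if taken >= n_per_linker:
                break
            a, b, pa, pb = eligible[int(i)]
            comps = tuple(sorted((pa, pb), key=lambda p: (p.start, p.sequence)))
            key = ("inter", comps[0].start, comps[1].start, linker.name)
            if key in seen_keys:
                continue
            seen_keys.add(key)
            taken += 1
            sites = tuple(
                peptide_reactive_sites(p, linker, cfg.protein_start) for p in comps)
            cand = CandidateConjugate(
                "inter", comps, linker.name, "light",
                conjugate_mass(comps, linker, "light"), sites)
            conjugates.append(cand)
            pairs.append((a, b))
            fractions.append(cfg.mixing_fractions[k % len(cfg.mixing_fractions)])
            k += 1
    return conjugates, pairs, fractions


# ---------------------------------------------------------------------------
# Peak lists

def _decoy_masses(rng: np.random.Generator, n: int, lo: float, hi: float,
                  avoid: np.ndarray, min_ppm: float) -> np.ndarray:
    out: list[float] = []
    for _ in range(100000):
        if len(out) >= n:
            break
        m = float(rng.uniform(lo, hi))
        if np.min(np.abs(avoid - m) / avoid) * 1e6 >= min_ppm:
            out.append(m)
    if len(out) < n:
        raise RuntimeError("decoy placement infeasible with the given ppm exclusion")
    return np.asarray(out)


def gen_peaklists(
    truth_conjugates: list[CandidateConjugate],
    fractions: list[float],
    cfg: ScenarioConfig,
    linkers: dict[str, CrosslinkerDef] | None = None,
) -> list[pd.DataFrame]:
    """Mixed d0/d4 peak lists, one per replicate.

    Each planted conjugate contributes a doublet: light at its theoretical
    mass, heavy at +4.0251 Da, with channel intensities drawn so the
    expected light share equals the configured mixing fraction, both masses
    perturbed by Gaussian ppm noise. Decoy masses are kept at least
    ``decoy_min_ppm`` away from every true mass (both isotope forms).
    """
    linkers = linkers or {"DSG": DSG, "DSS": DSS}
    rng = _rng(cfg, salt=4)
    light = np.array([c.mass for c in truth_conjugates])
    delta = {name: doublet_delta(l) for name, l in linkers.items()}
    heavy = np.array([c.mass + delta[c.linker] for c in truth_conjugates])
    avoid = np.concatenate([light, heavy]) if len(light) else np.array([1000.0])
    sigma_ln = math.sqrt(math.log(1 + cfg.intensity_cv**2))

    replicates = []
    for _rep in range(cfg.n_replicates):
        rows = []
        for c, f, ml, mh in zip(truth_conjugates, fractions, light, heavy):
            noise_l = ml * (1 + rng.normal(0, cfg.ppm_noise_sd) * 1e-6)
            noise_h = mh * (1 + rng.normal(0, cfg.ppm_noise_sd) * 1e-6)
            il = cfg.base_intensity * f * rng.lognormal(-sigma_ln**2 / 2, sigma_ln)
            ih = cfg.base_intensity * (1 - f) * rng.lognormal(-sigma_ln**2 / 2, sigma_ln)
            rows.append({"mass": noise_l, "intensity": il})
            rows.append({"mass": noise_h, "intensity": ih})
        if cfg.n_decoys:
            lo, hi = float(avoid.min()) * 0.8, float(avoid.max()) * 1.2
            for m in _decoy_masses(rng, cfg.n_decoys, lo, hi, avoid, cfg.decoy_min_ppm):
                rows.append({"mass": m, "intensity": float(rng.uniform(0.01, 0.2) * cfg.base_intensity)})
        df = pd.DataFrame(rows, columns=["mass", "intensity"]).sort_values("mass").reset_index(drop=True)
        replicates.append(df)
    return replicates


# ---------------------------------------------------------------------------
# HDX kinetics

def protection_factors(cfg: ScenarioConfig, sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Two-state per-residue protection: complex raised in the planted region."""
    n = len(sequence)
    free = np.full(n, cfg.protection_free, dtype=float)
    comp = free.copy()
    lo, hi = cfg.protected_region
    for i in range(n):
        pos = cfg.protein_start + i
        if lo <= pos <= hi:
            comp[i] = free[i] * cfg.protection_complex_factor
    return free, comp


def residue_uptake_truth(p_factors: np.ndarray, t: float, k_int: float) -> np.ndarray:
    """u_i(t) = 1 - exp(-k_int * t / P_i)."""
    if np.any(p_factors <= 0):
        raise ValueError("protection factors must be positive")
    return 1.0 - np.exp(-k_int * t / p_factors)


def hdx_peptide_pool(sequence: str, protein_start: int = 1,
                     lengths: tuple[int, ...] = (8, 12), step: int = 1) -> list[PeptideSpecies]:
    """Deterministic overlapping peptide map emulating nonspecific proteolysis.

    The default single-residue stagger of the short windows makes
    shortest-fragment consolidation exactly invertible everywhere past the
    first window, which is what lets noiseless scenarios reproduce the
    planted per-residue truth.
    """
    n = len(sequence)
    pool: list[PeptideSpecies] = []
    seen = set()
    for L in lengths:
        for s in range(0, max(n - L + 1, 1), step):
            e = min(s + L, n)
            key = (s, e)
            if key in seen or e - s < 3:
                continue
            seen.add(key)
            pool.append(PeptideSpecies(sequence[s:e], s + protein_start, e + protein_start - 1))
        # always include a fragment flush with the C-terminus
        s = max(n - L, 0)
        if (s, n) not in seen:
            seen.add((s, n))
            pool.append(PeptideSpecies(sequence[s:n], s + protein_start, n + protein_start - 1))
    pool.sort(key=lambda p: (p.start, p.end))
    return pool


def gen_hdx(
    sequence: str,
    cfg: ScenarioConfig,
    pool: list[PeptideSpecies] | None = None,
) -> tuple[list[UptakeRecord], dict[str, float], dict[str, np.ndarray]]:
    """Centroid records for both states, all timepoints and replicates.

    Peptide centroid = undeuterated mass + sum of residue uptakes over the
    peptide's exchangeable positions (+ optional Gaussian noise). Returns
    (records, undeuterated controls, truth per-residue uptake arrays keyed
    "state@time").
    """
    rng = _rng(cfg, salt=5)
    pool = pool or hdx_peptide_pool(sequence, cfg.protein_start)
    p_free, p_comp = protection_factors(cfg, sequence)
    controls = {
        f"{p.sequence}({p.start}-{p.end})": peptide_mass(p) for p in pool
    }
    records: list[UptakeRecord] = []
    truth: dict[str, np.ndarray] = {}
    for state, pf in (("free", p_free), ("complex", p_comp)):
        for t in cfg.timepoints:
            u = residue_uptake_truth(pf, t, cfg.k_int)
            truth[f"{state}@{t}"] = u
            for rep in range(cfg.n_replicates):
                for p in pool:
                    exch = exchangeable_positions(p)
                    uptake = sum(u[pos - cfg.protein_start] for pos in exch)
                    centroid = controls[f"{p.sequence}({p.start}-{p.end})"] + uptake
                    if cfg.hdx_noise_sd > 0:
                        centroid += rng.normal(0, cfg.hdx_noise_sd)
                    records.append(UptakeRecord(p, state, t, rep, centroid))
    return records, controls, truth


# ---------------------------------------------------------------------------
# Scenario materialization

def build_scenario(cfg: ScenarioConfig):
    """Generate the complete ground-truth scenario in memory."""
    sequence = cfg.protein_sequence or random_protein(cfg)
    coords = gen_fold(ScenarioConfig(**{**asdict(cfg), "protein_sequence": sequence}))
    conjugates, pairs, fractions = plant_crosslinks(coords, sequence, [DSG, DSS], cfg)
    peaklists = gen_peaklists(conjugates, fractions, cfg)
    hdx_records, controls, hdx_truth = gen_hdx(sequence, cfg)
    duplex = gen_duplex_coords(
        min(len(cfg.forward_strand), len(cfg.reverse_strand)),
        origin=coords.mean(axis=0) + np.array([18.0, 0.0, 0.0]))
    truth = GroundTruth(
        sequence=sequence, protein_start=cfg.protein_start, coords=coords,
        conjugates=conjugates, site_pairs=pairs, mixing_fractions=fractions,
        protection_free=protection_factors(cfg, sequence)[0],
        protection_complex=protection_factors(cfg, sequence)[1])
    return {
        "config": cfg,
        "truth": truth,
        "peaklists": peaklists,
        "hdx_records": hdx_records,
        "hdx_controls": controls,
        "hdx_truth": hdx_truth,
        "duplex": duplex,
    }


def write_scenario(outdir, cfg: ScenarioConfig) -> dict:
    """Materialize a scenario directory (FASTA, CSVs, PDB, manifest)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sc = build_scenario(cfg)
    truth: GroundTruth = sc["truth"]

    (out / "protein.fasta").write_text(f">protein\n{truth.sequence}\n")
    (out / "duplex.fasta").write_text(
        f">forward\n{cfg.forward_strand}\n>reverse\n{cfg.reverse_strand}\n")
    for i, df in enumerate(sc["peaklists"]):
        df.to_csv(out / f"peaklist_rep{i}.csv", index=False)
    rows = [
        {"peptide": f"{r.peptide.sequence}({r.peptide.start}-{r.peptide.end})",
         "sequence": r.peptide.sequence, "start": r.peptide.start, "end": r.peptide.end,
         "state": r.state, "timepoint": r.timepoint, "replicate": r.replicate,
         "centroid": r.centroid}
        for r in sc["hdx_records"]
    ]
    pd.DataFrame(rows).to_csv(out / "hdx_centroids.csv", index=False)
    pd.DataFrame(
        [{"peptide": k, "centroid_m0": v} for k, v in sc["hdx_controls"].items()]
    ).to_csv(out / "hdx_controls.csv", index=False)
    st = fold_to_structure(truth.coords, truth.sequence, truth.protein_start,
                           duplex=sc["duplex"], forward=cfg.forward_strand,
                           reverse=cfg.reverse_strand)
    st.setup_entities()
    doc = st.make_pdb_string()
    (out / "fold.pdb").write_text(doc)
    manifest = {
        "seed": cfg.seed,
        "protein_length": len(truth.sequence),
        "protein_start": truth.protein_start,
        "n_planted_conjugates": len(truth.conjugates),
        "planted": [
            {"label": c.label(), "mass": c.mass, "site_pair": list(p), "fraction": f}
            for c, p, f in zip(truth.conjugates, truth.site_pairs, truth.mixing_fractions)
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return sc
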