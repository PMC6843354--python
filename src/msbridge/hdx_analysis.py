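"""Hydrogen-deuterium exchange uptake analysis.

Peptide-level centroid time courses from free and DNA-bound samples are
turned into relative deuteration (DR, the deuterated fraction of
exchangeable backbone amides), consolidated to residue level by ordered
subtraction of overlapping peptides, differenced between states, and
classified; residues protected upon binding are exported as docking-active
residues.

Exchangeable amides: every backbone amide except the peptide's first
residue (whose deuterium is lost too fast to observe) and prolines (no
amide hydrogen). The alternative convention that discards the first two
residues is available via ``skip_residues=2``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_masses import PeptideSpecies

logger = logging.getLogger(__name__)

#: exchange-reaction sampling schedule (minutes)
DEFAULT_TIMEPOINTS = (0.33, 2.0, 5.0, 10.0, 30.0, 60.0, 180.0, 300.0)


@dataclass(frozen=True)
class UptakeRecord:
    """One centroid observation for one peptide/state/timepoint/replicate."""

    peptide: PeptideSpecies
    state: str               # "free" | "complex"
    timepoint: float         # minutes
    replicate: int
    centroid: float          # observed centroid mass (Da)


@dataclass(frozen=True)
class ResidueUptake:
    """Residue-level relative deuteration after consolidation."""

    position: int
    state: str
    timepoint: float
    dr: float
    uncertainty: float = 0.0


def exchangeable_positions(p: PeptideSpecies, skip_residues: int = 1) -> tuple[int, ...]:
    """Construct positions of the peptide's exchangeable backbone amides."""
    return tuple(
        p.start + i
        for i in range(skip_residues, len(p.sequence))
        if p.sequence[i] != "P"
    )


def exchangeable_count(p: PeptideSpecies, skip_residues: int = 1) -> int:
    """Number of exchangeable amide hydrogens in the peptide."""
    n = len(exchangeable_positions(p, skip_residues))
    if n == 0:
        logger.warning("peptide %s has no exchangeable amides", p.sequence)
    return n


def relative_uptake(
    rec_t: UptakeRecord,
    rec_0: UptakeRecord | float,
    n_ex: int,
) -> float:
    """Relative deuteration DR = (m_t - m_0) / N_ex, clamped to [0, 1].

    ``rec_0`` may be the undeuterated control record or its centroid mass.
    Clamping events are logged, never silent.
    """
    if n_ex <= 0:
        raise ValueError("peptide has no exchangeable amides (N_ex = 0)")
    m0 = rec_0.centroid if isinstance(rec_0, UptakeRecord) else float(rec_0)
    dr = (rec_t.centroid - m0) / n_ex
    if dr < 0.0 or dr > 1.0:
        logger.info(
            "DR %.4f clamped for peptide %s at t=%.2f", dr,
            rec_t.peptide.sequence, rec_t.timepoint)
        dr = min(max(dr, 0.0), 1.0)
    return dr


@dataclass
class ConsolidationResult:
    residues: list[ResidueUptake]
    residuals: dict[str, float]      # peptide label -> unexplained uptake (Da)
    n_clamped: int


def residue_consolidation(
    peptide_uptakes: list[tuple[PeptideSpecies, float]],
    state: str = "",
    timepoint: float = 0.0,
    skip_residues: int = 1,
    tol: float = 1e-9,
) -> ConsolidationResult:
    """Distribute peptide-level uptake (Da) onto individual residues.

    Deterministic shortest-fragment-first subtraction: peptides are
    processed in order of increasing length (then start position); the
    uptake already attributed to a peptide's resolved residues is
    subtracted and the remainder spread uniformly over its still-unresolved
    exchangeable positions. Residues of an unresolved segment therefore
    share one value. Negative remainders beyond tolerance are flagged and
    clamped to zero; per-peptide residuals report how consistently the
    overlaps closed.
    """
    resolved: dict[int, float] = {}
    n_clamped = 0
    ordered = sorted(peptide_uptakes, key=lambda t: (len(t[0]), t[0].start))
    for p, uptake in ordered:
        exch = exchangeable_positions(p, skip_residues)
        if not exch:
            continue
        unknown = [pos for pos in exch if pos not in resolved]
        remainder = uptake - sum(resolved.get(pos, 0.0) for pos in exch if pos in resolved)
        if not unknown:
            continue
        if remainder < -tol:
            logger.warning(
                "contradictory overlaps at peptide %s (%d-%d): remainder %.4g clamped to 0",
                p.sequence, p.start, p.end, remainder)
            n_clamped += 1
            remainder = 0.0
        per_residue = max(remainder, 0.0) / len(unknown)
        if per_residue > 1.0 + tol:
            logger.warning("per-residue uptake %.4f > 1 clamped in segment %s", per_residue, unknown)
            n_clamped += 1
            per_residue = 1.0
        for pos in unknown:
            resolved[pos] = per_residue

    residuals: dict[str, float] = {}
    for p, uptake in ordered:
        exch = exchangeable_positions(p, skip_residues)
        explained = sum(resolved.get(pos, 0.0) for pos in exch)
        residuals[f"{p.sequence}({p.start}-{p.end})"] = uptake - explained

    residues = [
        ResidueUptake(position=pos, state=state, timepoint=timepoint, dr=val)
        for pos, val in sorted(resolved.items())
    ]
    return ConsolidationResult(residues=residues, residuals=residuals, n_clamped=n_clamped)


def differential(
    free: list[ResidueUptake],
    complexed: list[ResidueUptake],
    k_sd: float = 2.0,
    min_sd: float = 0.02,
) -> pd.DataFrame:
    """Per-residue, per-timepoint deuteration difference free - complex.

    The two inputs must cover the same (residue, timepoint) grid; missing
    cells are an error listing the offenders. Significance requires
    |delta| > k_sd * pooled uncertainty, where the pooled value is floored
    at ``min_sd`` DR units so noiseless data is not flagged wholesale.
    """
    f = {(r.position, r.timepoint): r for r in free}
    c = {(r.position, r.timepoint): r for r in complexed}
    missing = sorted(set(f) ^ set(c))
    if missing:
        raise ValueError(f"residue/timepoint grids differ; unmatched cells: {missing[:10]}")
    rows = []
    for key in sorted(f):
        rf, rc = f[key], c[key]
        delta = rf.dr - rc.dr
        pooled = max(math.hypot(rf.uncertainty, rc.uncertainty), min_sd)
        rows.append({
            "residue": key[0],
            "timepoint": key[1],
            "delta_dr": delta,
            "pooled_sd": pooled,
            "significant": abs(delta) > k_sd * pooled,
        })
    return pd.DataFrame(rows, columns=["residue", "timepoint", "delta_dr", "pooled_sd", "significant"])


def classify_time_course(series: list[float], noise_tol: float = 0.05) -> str:
    """Shape label for a difference time course.

    "flat" when every value stays inside the noise band; otherwise the sign
    pattern of successive differences (with the same tolerance) selects
    "rising-saturating" (no significant decrease), "rise-then-fall"
    (increase followed only by decrease), or "other".
    """
    if len(series) < 4:
        raise ValueError("need at least 4 timepoints to classify a time course")
    v = np.asarray(series, dtype=float)
    if np.all(np.abs(v) < noise_tol):
        return "flat"
    diffs = np.diff(v)
    signs = [1 if d > noise_tol else -1 if d < -noise_tol else 0 for d in diffs]
    nonzero = [s for s in signs if s != 0]
    if not nonzero:
        return "flat"
    if all(s >= 0 for s in signs):
        return "rising-saturating"
    first_neg = signs.index(-1)
    if 1 in signs[first_neg:]:
        return "other"
    if 1 in signs[:first_neg]:
        return "rise-then-fall"
    return "other"


def export_active_residues(profile: pd.DataFrame, threshold: float = 0.0) -> list[int]:
    """Docking-active residues: significantly protected upon binding.

    A residue qualifies when it shows a significant positive deuteration
    difference exceeding ``threshold`` at one or more timepoints.
    """
    mask = profile["significant"] & (profile["delta_dr"] > threshold) & (profile["delta_dr"] > 0)
    return sorted(profile.loc[mask, "residue"].unique().tolist())


# ---------------------------------------------------------------------------
# Table-level drivers

def uptake_from_centroids(
    records: list[UptakeRecord],
    controls: dict[str, float],
    skip_residues: int = 1,
) -> pd.DataFrame:
    """Per-peptide DR table from raw centroid records.

    ``controls`` maps peptide label -> undeuterated centroid mass.
    Replicates are averaged; mean and sample sd of DR are reported.
    """
    by_key: dict[tuple, list[float]] = {}
    peptides: dict[str, PeptideSpecies] = {}
    for rec in records:
        label = f"{rec.peptide.sequence}({rec.peptide.start}-{rec.peptide.end})"
        peptides[label] = rec.peptide
        n_ex = exchangeable_count(rec.peptide, skip_residues)
        dr = relative_uptake(rec, controls[label], n_ex)
        by_key.setdefault((label, rec.state, rec.timepoint), []).append(dr)
    rows = []
    for (label, state, t), drs in sorted(by_key.items()):
        arr = np.asarray(drs)
        p = peptides[label]
        rows.append({
            "peptide": label, "start": p.start, "end": p.end,
            "state": state, "timepoint": t,
            "dr_mean": float(arr.mean()),
            "dr_sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "n_replicates": len(arr),
        })
    return pd.DataFrame(rows, columns=[
        "peptide", "start", "end", "state", "timepoint",
        "dr_mean", "dr_sd", "n_replicates"])
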