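"""In-silico digestion and duplex handling.

Covers tryptic proteolysis with missed cleavages, a Bal-31 nuclease
fragment model for trimming the oligonucleotide moiety of peptide-DNA
conjugates, ungapped duplex annealing, motif location, and peptide-map
coverage statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .chem_masses import (
    AA_COMPOSITIONS,
    NUCLEOSIDE_COMPOSITIONS,
    OligoSpecies,
    PeptideSpecies,
    peptide_mass,
)

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class DigestConfig:
    """Bounds for proteolytic and nucleolytic digestion products."""

    max_missed_cleavages: int = 2
    min_peptide_length: int = 1
    max_peptide_length: int = 10**6
    min_oligo_length: int = 1
    bal31_model: str = "substring"   # or "end-truncation"
    cleave_before_proline: bool = False

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0 or self.min_peptide_length < 0:
            raise ValueError("digestion bounds must be non-negative")
        if self.min_peptide_length > self.max_peptide_length:
            raise ValueError("min peptide length exceeds max")
        if self.bal31_model not in ("substring", "end-truncation"):
            raise ValueError(f"unknown Bal-31 model {self.bal31_model!r}")


@dataclass(frozen=True)
class DuplexRecord:
    """Result of ungapped annealing of two strands."""

    forward: str
    reverse: str
    offset: int
    paired_positions: int


def reverse_complement(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq))
    except KeyError as e:
        raise ValueError(f"non-ACGT symbol {e.args[0]!r} in DNA sequence") from None


def trypsin_digest(sequence: str, cfg: DigestConfig | None = None) -> list[PeptideSpecies]:
    """Tryptic peptides with 0..max missed cleavages.

    Cleaves C-terminal to K/R, suppressed when the next residue is proline
    (switchable via the config). Positions are 1-based inclusive in the
    input numbering.
    """
    cfg = cfg or DigestConfig()
    if not sequence:
        raise ValueError("protein sequence must be non-empty")
    for ch in sequence:
        if ch not in AA_COMPOSITIONS:
            raise ValueError(f"unknown amino-acid symbol {ch!r}")
    # cleavage sites: index i means a cut between sequence[i-1] and sequence[i]
    cuts = [0]
    for i in range(1, len(sequence)):
        if sequence[i - 1] in "KR" and (cfg.cleave_before_proline or sequence[i] != "P"):
            cuts.append(i)
    cuts.append(len(sequence))

    peptides: list[PeptideSpecies] = []
    for i in range(len(cuts) - 1):
        for missed in range(cfg.max_missed_cleavages + 1):
            j = i + 1 + missed
            if j >= len(cuts):
                break
            start, end = cuts[i], cuts[j]
            if not cfg.min_peptide_length <= end - start <= cfg.max_peptide_length:
                continue
            peptides.append(
                PeptideSpecies(
                    sequence=sequence[start:end],
                    start=start + 1,
                    end=end,
                    missed_cleavages=missed,
                )
            )
    return peptides


def bal31_fragments(
    strand: str,
    cfg: DigestConfig | None = None,
    strand_label: str = "forward",
    five_prime: str = "OH",
    three_prime: str = "OH",
) -> list[OligoSpecies]:
    """Oligonucleotide fragments left by Bal-31 trimming.

    The default "substring" model enumerates every contiguous subsequence of
    length >= the configured minimum — a deliberate superset so that library
    matching never misses a true conjugate. The "end-truncation" mode keeps
    only fragments retaining at least one original terminus.
    """
    cfg = cfg or DigestConfig()
    for ch in strand:
        if ch not in NUCLEOSIDE_COMPOSITIONS:
            raise ValueError(f"non-ACGT symbol {ch!r} in DNA strand")
    n = len(strand)
    m = cfg.min_oligo_length
    frags: list[OligoSpecies] = []
    for start in range(n):
        for end in range(start + m, n + 1):
            if cfg.bal31_model == "end-truncation" and start != 0 and end != n:
                continue
            frags.append(
                OligoSpecies(
                    sequence=strand[start:end],
                    strand=strand_label,
                    start=start + 1,
                    end=end,
                    five_prime=five_prime,
                    three_prime=three_prime,
                )
            )
    return frags


def anneal(forward: str, reverse: str) -> DuplexRecord:
    """Best ungapped Watson-Crick pairing of two strands.

    Slides the reverse complement of ``reverse`` along ``forward`` and
    reports the offset maximizing the number of complementary positions.
    """
    rc = reverse_complement(reverse)
    for ch in forward:
        if ch not in COMPLEMENT:
            raise ValueError(f"non-ACGT symbol {ch!r} in DNA sequence")
    best_offset, best_pairs = 0, -1
    for offset in range(-(len(rc) - 1), len(forward)):
        pairs = 0
        for i, base in enumerate(rc):
            j = offset + i
            if 0 <= j < len(forward) and forward[j] == base:
                pairs += 1
        if pairs > best_pairs:
            best_offset, best_pairs = offset, pairs
    return DuplexRecord(forward=forward, reverse=reverse,
                        offset=best_offset, paired_positions=best_pairs)


def find_motif(strand: str, motif: str, search_reverse_complement: bool = False) -> list[int]:
    """1-based start positions of exact (overlapping) motif occurrences."""
    if not motif:
        raise ValueError("motif must be non-empty")
    targets = [motif]
    if search_reverse_complement:
        targets.append(reverse_complement(motif))
    hits = set()
    for t in targets:
        for i in range(len(strand) - len(t) + 1):
            if strand[i : i + len(t)] == t:
                hits.add(i + 1)
    return sorted(hits)


@dataclass(frozen=True)
class CoverageMap:
    depth: np.ndarray
    coverage_percent: float
    mean_redundancy: float


def coverage_map(peptides: list[PeptideSpecies], sequence: str) -> CoverageMap:
    """Per-residue peptide depth, % coverage, and mean redundancy."""
    depth = np.zeros(len(sequence), dtype=int)
    for p in peptides:
        if p.start < 1 or p.end > len(sequence):
            raise ValueError(
                f"peptide {p.sequence} ({p.start}-{p.end}) outside sequence bounds 1-{len(sequence)}"
            )
        depth[p.start - 1 : p.end] += 1
    coverage = 100.0 * float(np.count_nonzero(depth)) / len(sequence) if len(sequence) else 0.0
    return CoverageMap(depth=depth, coverage_percent=coverage,
                       mean_redundancy=float(depth.mean()) if len(sequence) else 0.0)


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def digest_table(peptides: list[PeptideSpecies]) -> pd.DataFrame:
    """Tabulate a digest (sequence, positions, missed cleavages, mass)."""
    rows = [
        {
            "sequence": p.sequence,
            "start": p.start,
            "end": p.end,
            "missed_cleavages": p.missed_cleavages,
            "mass": round(peptide_mass(p), 6),
        }
        for p in peptides
    ]
    return pd.DataFrame(rows, columns=["sequence", "start", "end", "missed_cleavages", "mass"])
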