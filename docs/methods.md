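# Methods note

This note records the models, parameter values, numerical conventions and
design decisions implemented in `msbridge`, and the known limitations of its
synthetic-data generator. All numbers stated here are the package's inputs or
conventions, not empirical claims.

## Mass model

All masses are monoisotopic and computed from explicit elemental composition
tables (`chem_masses.ELEMENT_MASSES`), e.g. H = 1.00782503207, D (²H) =
2.01410177785, C = 12 exactly, N = 14.0030740048, O = 15.9949146196,
Cl = 34.96885268. Platinum species default to ¹⁹⁵Pt = 194.9647911 (the most
abundant isotope); ¹⁹⁴Pt is available and the choice is recorded on the adduct
definition, since "monoisotopic" is ambiguous for Pt without declaring the
reference isotope.

- Peptide mass = Σ residue compositions + H₂O; terminal modifications are
  composition deltas.
- Oligonucleotide mass = Σ nucleoside compositions + (n−1)·(HPO₃) condensation
  (each internal phosphodiester adds HPO₃ and removes H₂O relative to free
  nucleosides), plus HPO₃ per phosphorylated terminus. Default termini are
  5′-OH/3′-OH.
- NHS-ester bridges: DSG = C₅H₄O₂ (light), heavy form C₅D₄O₂ (all four
  hydrogens deuterated); DSS = C₈H₁₀O₂ (light), heavy form C₈H₆D₄O₂ (four
  hydrogens deuterated). The d4/d0 spacing is
  therefore 4·(m(D)−m(H)) = 4.0251 Da, nominally 4 Da. Mono-links add one
  bridge + H₂O (hydrolyzed second arm).
- Transplatin: bifunctional bridge = Pt(NH₃)₂ (both chlorides displaced),
  delta 229.0180 Da; monofunctional "dangling" adduct = Pt(NH₃)₂Cl,
  delta 263.9867 Da. Reactive classes: Lys/Ser (+ protein N-terminus) for
  NHS esters; Cys/Met/His/Thr on protein and guanine N7 on DNA for Pt.

ppm error is defined as (observed − theoretical)/theoretical × 10⁶; the
default matching tolerance is 5 ppm throughout.

## Digestion and annealing

Trypsin cleaves after Lys/Arg but not before Pro; missed cleavages up to a
configurable maximum (default 2 in the digestion module, 1 in the pipeline
driver) are generated by concatenating adjacent fully cleaved peptides.
Bal-31 trimming of the oligonucleotide moiety is modeled as the set of all
substrings above a minimum length (an "end-truncation" variant that keeps one
original terminus is available); the substring model yields
(n−m+1)(n−m+2)/2 fragments of length ≥ m from an n-mer.

Annealing is ungapped: one strand is slid against the reverse complement of
the other and the offset maximizing Watson–Crick matches is reported. The two
built-in strands (5′-TTGGGTAAACAAG-3′ / 5′-CTTGTTTACCCAA-3′) form a 13 bp
duplex at offset 0; the recognition motif TTGTTTAC occurs at position 2 of
the second strand.

## Identification and quantification

The candidate library enumerates inter-peptide (unordered pairs), loop
(≥2 sites within one peptide), mono-link and peptide–DNA (Pt) conjugates for
each isotope form. Matching uses a sorted-mass window (binary search) and
ranks candidates by |ppm error|, then fewer components, then label — a total
order, so results are deterministic. Pt conjugates are reported
composition-only: the Pt bridge dissociates in the gas phase and provides no
site-localizing fragments, so localization claims are restricted to the
reactive-class inventory.

Doublet quantification pairs each light peak with the single unused peak
nearest to light + 4.0251 Da within tolerance, processing peaks in descending
intensity (greedy, single-use). The free fraction is
I_light/(I_light+I_heavy)·100. Replicates aggregate with the sample standard
deviation (ddof = 1); a single replicate is flagged rather than given a fake
uncertainty. Differential direction uses |Δ from 50 %| with a 10-point
"unchanged" band by default.

## HDX

Exchangeable amides: every backbone amide except the peptide's first residue
(back-exchange too fast; a skip-2 convention is selectable) and prolines.
DR = (m_t − m_0)/N_ex, clamped to [0, 1] with a logged warning — clamping is
never silent. Residue consolidation distributes peptide uptake (Da) by
deterministic shortest-fragment-first subtraction: a peptide's uptake minus
what its already-resolved residues explain is spread uniformly over its
unresolved exchangeable positions. With a single-residue-staggered peptide
map this inversion is exact; per-peptide residuals report how consistently
overlaps closed. Differential profiles (free − complex) require identical
residue/timepoint grids and flag |Δ| > k·pooled-sd (k = 2) with the pooled
uncertainty floored at 0.02 DR so noiseless data is not flagged wholesale.
Docking-active residues are those with a significant positive protection at
any timepoint.

## Restraints

A cross-link implies an upper bound span + tolerance on the separation of the
bridged residues: DSG 20.5 Å, DSS 24.2 Å, both ±3.0 Å (spans include
side-chain allowance). The Pt bridge span of 5.0 ± 2.0 Å is a package default
chosen from the short Pt–N coordination geometry, not an experimentally
calibrated value. Measurement atoms default to Cα for amino acids and N7 for
guanine (N1 otherwise) — declared, not guessed per structure. Ambiguous
groups (multiple candidate sites, composition-only Pt conjugates) are
satisfied if any member pair is. Unresolvable endpoints are reported as
not-evaluable, never dropped silently. Distance-set comparison reports
per-pair deltas and their RMSD. Exports: TSV (round-trippable), CNS assign
statements, HADDOCK-style ambiguous blocks; output ordering is deterministic
so repeated export is byte-identical.

## Synthetic generator

The scenario generator fabricates: a random sequence with a cleavage site
roughly every 8 residues; a self-avoiding random Cα chain (3.8 Å steps,
3.9 Å excluded radius); an ideal B-form duplex (3.4 Å rise, 36° twist,
antiparallel pairing); cross-links planted only between reactive residues of
different tryptic peptides that are genuinely within span on that fold; peak
lists with Gaussian ppm noise (default σ = 1 ppm), lognormal intensity noise
(cv = 0.05), d0/d4 doublets at configured mixing fractions (defaults 0.959,
0.728, 0.5), and ≥ 50 ppm-separated decoys; and two-state HDX kinetics
u_i(t) = 1 − exp(−k_int·t/P_i) with a protection factor raised 100-fold
inside a planted region (construct residues 103–130 by default; the default
construct is 134 residues numbered 74–207). All randomness flows through
`numpy.random.default_rng` seeded per-purpose from the scenario seed, so a
config + seed fully determines every output.

Generator limitations, deliberately accepted:

- The fold is a self-avoiding walk, not a physical protein model; planted
  distances are geometric, with no secondary structure or side chains.
- Structures carry one reference atom per residue (Cα / N7 / N1); restraint
  measurement on real all-atom structures works through the same code path
  but the synthetic PDBs are stand-ins only.
- HDX kinetics are single-exponential per residue with uniform intrinsic
  rates; no EX1 behavior, no sequence-dependent intrinsic-rate model, no
  back-exchange model.
- Intensity noise is independent per channel; no correlated ionization or
  detector effects. Near-isobaric planted conjugates can legitimately create
  ambiguous mass-only matches — the pipeline reports these honestly rather
  than resolving them with information it does not have.
- Intact-mass ladders for the annotate stage are idealized (fixed adduct
  ladder, deterministic intensities).

## Numerical conventions

- Elemental masses are stored to the precision above; conjugate arithmetic is
  plain float64 summation (species contain tens of atoms of each element, far
  from accumulation-error territory at the 1e-6 Da level asserted in tests).
- Sample statistics use ddof = 1; RMSD is the root of the mean squared delta
  over evaluable pairs only.
- ppm windows are evaluated against the theoretical mass in the denominator.
- All tabular outputs have fixed column orders and deterministic row
  ordering; manifests record SHA-256 hashes of every input and output file.

## Design decisions

- Compositions over averaged masses everywhere; no average-mass mode exists.
- The Pt isotope choice is an explicit field, defaulted to ¹⁹⁵Pt.
- Mono-links are retained in libraries (they are real species competing for
  matches) but contribute no distance restraints.
- The greedy doublet pairing is intentionally simple and auditable; a global
  assignment would change results only in pathological overlap cases, which
  the generator can produce and the tests treat as honest ambiguity.
- `biopython` reads FASTA, `gemmi` reads/writes structures, `pandas` carries
  tables; mass arithmetic itself is first-party because the composition
  conventions (termini, bridges, Pt isotopes) are the point of the package.
  `pyteomics` is used in the test suite only, as an independent oracle.
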