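# Methods

## Motif grammar and classification

The scanner tests every 5-residue window ψΘxxΓ against fixed residue-class
sets: ψ ∈ {D, E} (acidic), or phospho-S/T (phospho), or — only when
`allow_conditional` is set — unmodified S/T (conditional); Θ ∈ {I, L, V, F,
Y, W}; Γ ∈ {L, I, V}; x unrestricted.  The LIR scanner is the same grammar
with Θ restricted to the aromatic subset {F, Y, W}, so LIR hits are a subset
of FIR hits by construction.  Phospho-Tyr is accepted by the parser but
never satisfies ψ: only Ser/Thr phosphorylation creates the anchor.  An
early narrower description of the core (Θ ∈ {I, W} with a doubled ψ) is
treated as a special case of this final grammar, not as a second grammar.

Mode assignment follows the anchor chemistry alone — Mode I for acidic ψ,
Mode II for phospho-S/T, `conditional_II` for unmodified S/T.  The acidic
extension is summarized over a window of 4 residues immediately N-terminal
of ψ (truncated at the sequence start; configurable): counts of D/E,
phospho-S/T, and unmodified S/T, with `acidic_ok` true when at least one
acidic or phospho residue is present.  Because the two binding modes are
both drawn with a preceding acidic element, a hit without one is *not*
suppressed; it is reported with mode unchanged and flagged "core-only,
low-confidence".  An S/T directly preceding ψ is flagged as an enhancer
site (a phosphorylatable position that strengthens either mode).  No
numeric composite score is invented — the experimental definition is a set
of criteria, not weights — so output is class/flag-based.  Overlapping
matches are all reported in ascending ψ position.

Indexing is 1-based throughout; protein coordinates are peptide position +
`numbering_offset` − 1 (e.g. the 15-mer CCPG1 context TASDDSDIVTLEPPK at
offset 99 puts ψ = D at 105; the Optineurin 13-mer SSEDSFVEIRMAE at offset
173 puts ψ = S at 177).

## Mass arithmetic

Monoisotopic residue masses (5-decimal table, cross-checked against
pyteomics in the test suite), water 18.010565 Da, proton 1.007276 Da, and
HPO3 79.966331 Da per phospho mark.  Ion m/z is (M + z·proton)/z.  Only the
HCD b/y series is produced (b_i = N-terminal residue sum; y_i = C-terminal
residue sum + water), giving the complementarity invariant b_i + y_{n−i} =
M + 2·proton.  Neutral-loss (−98 Da) and a/c/z ions are out of scope.  Peak
annotation assigns each theoretical ion its nearest peak within a ppm or Da
tolerance (ties broken toward higher intensity) and counts
*site-determining* matches: ions whose residue span separates the assigned
phospho position from at least one alternative S/T/Y candidate.  Full
precision is kept internally; rounding to two decimals happens only at the
presentation layer.

## One-site FP binding

The default model is the exact one-site ligand-depletion quadratic (negative
root); the simple hyperbola Pt/(Pt + Kd) is selectable and agrees with the
depletion form to well under 1% whenever Lt ≤ Kd/100 — which holds for all
affinities of this system at the assay's 0.25 µM labeled-peptide
concentration, so the choice is immaterial there and the depletion form is
simply the safer default.  Fitting is unweighted nonlinear least squares
over (Kd, A_free, A_bound) with a deterministic initializer (asymptotes from
the first/last mean signal, Kd from the Pt nearest half-signal) and
Kd ≥ 0 enforced by bounds; standard errors come from the Gauss–Newton
covariance rss/(N−3)·(JᵀJ)⁻¹ at the optimum.  Convergence is reported
honestly from the optimizer; fold-changes Kd_B/Kd_A carry first-order
propagated uncertainty.  Signal units are arbitrary (polarization or
anisotropy; no G-factor handling).

The titration presets encode the measured affinities of the study system as
simulation truths: 12 µM (phospho-Optineurin LIR vs FIP200 Claw), 307 µM
(unphosphorylated Optineurin LIR), 9 and 27 µM (CCPG1 FIR2 vs GABARAP with
and without pS104).  The design is 12 two-fold-spaced protein points from
0.5 µM (the 307 µM preset extends the same series one step, to ~2000 µM, so
the weak binder still reaches meaningful saturation), 3 replicates, and
homoscedastic Gaussian noise at 1% of the signal dynamic range — matching
the simple one-site fitting assumption of standard FP analysis.  The
recorded fold-change between the Optineurin truths is 307/12 ≈ 25.6; the
package reports the computed ratio as-is.

## Structure interfaces

SASA is Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points/atom; 3840 for high-accuracy runs), probe 1.4 Å, and
per-element radii C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å.  A
selection is treated as an isolated object, so the buried-area identity
BSA = SASA(A) + SASA(B) − SASA(A∪B) is exact and the per-residue
decomposition sums to it.  Because published interface areas are quoted in
both conventions, reports carry the summed value and its PISA-style half;
when calibrating against a reference complex, compute both once and apply
the matching convention uniformly.

Deposited crystal structures carry no hydrogens, so hydrogen bonds are
detected from heavy atoms: donor N/O (amide N except proline, plus
H-bearing side-chain N/O) to acceptor N/O within 3.5 Å, with the angle at
the donor — subtended by its nearest covalent heavy-atom antecedent —
at least 120°.  Both cutoffs are exposed because published bond counts
depend on the program used.  Salt bridges pair side-chain cations (Lys NZ;
Arg NE/NH1/NH2; His ND1/NE2) with anions (Asp OD1/2; Glu OE1/2; phosphate
O1P/O2P/O3P of SEP/TPO/PTR) within 4.0 Å.  Superposition is Kabsch via SVD
with an explicit degeneracy check (collinear or coincident point sets are
rejected).  Pocket contacts use the deposited Claw numbering (LHP 1565,
1567, 1574, 1576, 1582; SHG 1564, 1581) and a 4.5 Å heavy-atom cutoff; the
Claw chain is auto-detected as the chain containing the most pocket residue
numbers, since chain identifiers vary between depositions.

## Synthetic data: what it emulates, and what it does not

The generators produce every input class the pipeline consumes, each fully
determined by (parameters, seed) with truth emitted alongside the data:

* **Motif proteomes** — uniform background over the 20 amino acids with one
  grammar-satisfying core implanted per record (plus an acidic dipeptide
  before it, and a phospho-annotation row for Mode II implants).  Uniform
  background does not mimic real compositional bias or disorder propensity,
  and incidental background hits are possible; truth tables mark implants
  only, so exact-equality checks go through the brute-force window oracle.
* **FP titrations** — the one-site depletion curve plus homoscedastic
  Gaussian noise.  Real FP data can show signal-dependent variance, probe
  depletion artifacts, and pipetting error in Pt; none are modeled.
* **Spectra** — planted theoretical b/y peaks jittered within a stated ppm,
  with decoys rejected to lie > 3× the matching tolerance from every
  theoretical ion.  No isotope envelopes, noise floors, or co-eluting
  species.
* **Toy structures** — a sphere pair with closed-form SASA, an idealized
  antiparallel backbone pair whose strand stride (5 Å) is widened beyond
  real β-geometry so each amide N's covalent antecedent is unambiguous,
  giving an exact constructed H-bond ladder, and a mock Claw pocket with
  single-atom residues at the published numbering.

Passing tests therefore demonstrate correctness of the arithmetic,
geometry, grammar and estimation machinery under the stated models — not
performance on noisy proteome-scale annotation or on crystallographic
idiosyncrasies (altloc networks beyond occupancy rules, insertion-code
pathologies, modified residues other than SEP/TPO/PTR).

Quantities that require deposited coordinates (interface areas of the
published complexes, their hydrogen-bond counts) are computable with this
toolkit by pointing `firtool interface` at the corresponding PDB entries;
they are not part of the self-contained test surface, which instead
validates the geometry against closed-form and independent-implementation
oracles.

## Problem sizes in the default suite

Property checks run on 1000 random sequences (length ≤ 300) for the
scanner-vs-oracle equivalence, 1000 random peptides (length ≤ 30) for b/y
complementarity, 200 simulated titrations for the Kd bias sweep, and
3840-point SASA for oracle comparisons; the full suite completes in a few
seconds on one core.
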