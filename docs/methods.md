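# Methods

This note records the models, parameter choices and numerical conventions
behind `resurf`, and what the synthetic-data generators do and do not
emulate.

## Solvent accessibility

SASA is computed by Shrake–Rupley sphere sampling: each heavy atom is
expanded by the probe radius (default 1.4 Å, water) and covered with `n`
quasi-uniform points; a point survives if it lies outside every
neighbouring expanded sphere, and the accessible area is the surviving
fraction of the expanded sphere.  Points come from a golden-section
spiral — a deterministic lattice, so results are bit-stable across runs
and machines for a fixed `n`.  The default `n = 960` gives ≤0.2% error on
two-sphere closed-form benchmarks and exact results for isolated atoms;
error falls roughly as 1/n (verified on analytic oracles from 60 to 3840
points).  Neighbour search uses a k-d tree; the synthetic generator
recomputes its ground truth with plain quadratic-time loops so the two
paths check each other.

Radii are the per-element values of Bondi (1964), recorded in every
result's parameter block as `bondi64`.  Hydrogens are ignored throughout
(the target crystal structures carry none); hetero ligands and waters are
excluded by default and can be included as occluders via
`include_ligands=True`.

**RSASA.** Relative SASA divides a residue's summed atom SASA by a
published per-amino-acid maximum.  The default table is Miller et
al. (1987), computed for residue X in an extended Gly-X-Gly tripeptide.
We validated the pairing of table, radii and probe against the package's
own ideal-geometry extended-peptide builder: the central Ala of extended
Gly-Ala-Gly yields 112.7 Å², i.e. 0.997 of Miller's 113 Å² reference.  The
Tien et al. (2013) theoretical table — which maximises over conformers and
is therefore systematically higher (Ala 129 Å²) — ships as the named
alternative `tien2013-theoretical`.  RSASA values above 1.0 (termini,
unusually extended residues) are reported unclipped.

## Designability rule

A monomer position is **surface** when its RSASA strictly exceeds the
threshold (default 0.5) in its most-exposed chain copy — a homo-oligomer
is reported as a single per-monomer mask, and the most-permissive copy
determines exposure.  The **designable** set is the surface set plus any
position with a heavy atom within `neighbor_radius` (5 Å) of a surface
residue in any chain copy, minus positions within `active_site_radius`
(8 Å) of a declared active-site residue, minus positions whose minimum
heavy-atom distance to another chain falls below `interface_cutoff` (5 Å)
in any copy.  Interface membership in *any* copy excludes a position — the
conservative choice for an obligate oligomer.

Active-site positions are an input, never inferred; a documented default
list for *E. coli* type II asparaginase (mature-chain numbering 12, 25,
58, 59, 89, 90, 162) ships in `resurf.config`.  The proximity radii are
not uniquely fixed by any published protocol; reproducing a specific
study's designable-residue count is a calibration exercise over these
radii and the reference table, and the defaults above are our single
recorded choice, not a fit.  The expected anchor for the real enzyme —
78 of 326 monomer positions surface-exposed on the 3ECA homotetramer —
is encoded as an acceptance test that runs when a copy of that structure
is supplied (`tests/data/3eca.pdb`); the package does not redistribute
PDB entries.

## Variant metrics and panel selection

Mutational distance is the Hamming distance between equal-length monomer
sequences.  Integer percentages use half-up rounding (so 27/78 → 35%);
the total-percent denominator is the monomer length and the
surface-percent denominator is the number of surface positions.
Similarities (100 − exact percent) are kept at full precision and only
rounded for display.

Candidate proposal mutates only designable positions; substitutions are
drawn with probability proportional to a surrogate scorer.  The default
scorer is deliberately simple — BLOSUM62 log-odds restricted to
polar/charged surface-compatible residues (D,E,K,R,N,Q,S,T,H,G), shifted
positive — and is a stand-in interface for any structure- or ML-based
functional predictor a user may plug in; it encodes chemical plausibility,
not predicted function.

Panel selection is greedy max–min dispersion over Hamming distance
restricted to designable positions: seed with the pool member farthest
from wild type, then repeatedly add the candidate maximising its minimum
distance to the selected set, ties broken by pool order.  Greedy max–min
carries the classic factor-2 guarantee on the minimum pairwise distance;
an exhaustive search (pools ≤ 12) is included and used as the test
oracle.  QC triage applies the selection gates as strict inequalities
(>90% purity, >90% SEC, >5 nmol, >50% activity; <100 EU/mg endotoxin
only for the in-vivo tier).

## Assay analytics

*Background.* Each plate's mean secondary-only OD is subtracted from all
experimental and healthy-control wells of that plate.  Negative values
clamp to zero by default (OD is non-negative); `clamp_negative=False`
preserves them.

*Endpoint titer.* Technical replicates are averaged per dilution; the
titer is the largest dilution fold whose mean signal is at least
`factor` (default 3) times the healthy-control mean at that dilution,
with the control floored at a small configurable value so a zero control
cannot yield infinite ratios, and interpolated on log-dilution when its
grid differs.  The comparison is boundary-inclusive with a 1e-9 relative
tolerance so exact 3-fold ratios are not lost to floating point.

*Normalisation.* Percent-of-wild-type divides per-antigen means by the
wild-type mean; anti-His normalisation divides by the antigen's relative
coating factor.  The composition is invariant to any common
multiplicative plate gain.

*Outliers.* Two-sided Grubbs test with the t-distribution critical value
G(n, α) = ((n−1)/√n)·√(t²/(n−2+t²)), t = t₁₋α/(2n),n−2; optional
iterative removal.  The simulated null flag rate at α = 0.05, n = 8 is
5.0 ± 0.5% over 10,000 samples.  Robust-regression FDR screens (ROUT)
are not implemented; an external-flag hook covers workflows that use
them.

*Regression and ANOVA.* Binding-vs-distance is ordinary least squares
with the two-sided t-based slope p-value (p-values verified uniform under
a simulated null).  Hypersensitivity scores are compared per day by
one-way ANOVA of each arm against the wild-type arm; for two groups F
equals the squared equal-variance t statistic.  Following the common
reporting convention for such challenge studies, vs-wild-type contrasts
are unadjusted by default; Holm correction is available and off by
default.  Treating 0–4 ordinal scores as interval data is a deliberate
simplification matching field practice.

*Kinetics.* relVmax is the maximum slope over sliding 5-point linear
fits of the progress curve (2-minute read spacing assumed but not
required), optionally divided by a reference enzyme's value.  The window
default is an interpretation of "kinetic readout": long enough to
suppress single-read noise, short enough to stay inside the early linear
phase.

## Synthetic data: what it does and does not emulate

*Toy assemblies* are rings of rigid chain copies built from single-carbon
pseudo-residues with seeded jitter.  They reproduce the *geometry classes*
the mask logic must distinguish (exposed, partially buried, interface,
active-site-proximal positions) and come with brute-force ground truth,
but they are not proteins: no packing, no side chains, no real RSASA
spectrum.  Mask agreement on them validates the classification logic, not
the biological calibration of radii.

*ADA panels* posit a repertoire of `n_clones = 20` antibody clones, each
recognising an `epitope_size = 3` subset of the 78 surface positions; a
variant evades a clone if it mutates any epitope residue (all-or-nothing;
a graded-affinity alternative attenuates clones per hit).  Plate signal
follows a four-parameter logistic in dilution (top 3.0 OD, bottom 0.02,
EC50 at 1:30,000, Hill 1) spanning a 1:300–1:1,200,000 grid, with
multiplicative lognormal read noise (σ = 0.1) and an additive 0.05
background; technical triplicates throughout.  These defaults produce
titer and binding-decay structure of the kind observed in polyclonal ADA
studies, but the evasion mechanism is an invented minimal model — passing
recovery tests shows the analysis detects a monotone epitope-loss signal
at realistic noise, not that real repertoires behave this way.  The
`epitope_effect` dial exists solely to switch the generator into its null
(no-effect) regime for type-I-error checks.

*Hypersensitivity scores* come from a latent severity = 3.2 × residual
binding + N(0, 0.45), cut at thresholds (0.5, 1.5, 2.5, 3.5) into the 0–4
ordinal scale, with a ramped sensitisation phase and forced full
penetrance (score ≥ 1) at the third sensitising dose.  Arm sizes and
residual-binding levels in the examples and acceptance script mirror a
six-arm challenge design (vehicle/benchmark/three variants/wild type,
n = 5–10).

*Kinetics* are exponential-saturation progress curves
F(t) = Fmax(1 − e^(−vt/Fmax)) whose initial slope is exactly the true
velocity, with additive Gaussian noise.

All generators accept a seed, are reproducible to the byte, and return
their parameters as provenance metadata.

## Problem sizes in the standard runs

The test suite and acceptance script use: 200 simulated panels each for
regression power and for the null, 10,000 samples for the Grubbs null
rate, 2,000 replicates for p-value uniformity, 100 seeds for kinetic
ratio recovery and Spearman sign checks, 40 random pools (≤ 8 members)
for diversity-selection enumeration, and 960 sphere points for SASA.
These sizes give Monte-Carlo error comfortably below the asserted
tolerances and run in a few seconds on one CPU.

## Known limitations

- No structure repair, symmetry expansion, pocket detection or ΔΔG
  estimation; the deposited assembly is taken as the biological unit.
- The surrogate scorer is not a functional predictor; plug in a real one
  for design work.
- Grubbs assumes approximate normality and screens one outlier at a time;
  masked multiple outliers (demonstrated in the tests) need the iterative
  mode or an external method.
- ANOVA on ordinal scores and unadjusted multiple contrasts follow the
  reporting conventions of the motivating assays, not best statistical
  practice; the Holm option exists for the stricter reading.
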