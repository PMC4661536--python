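# Methods

This note records the models implemented in `nmrbind`, the defaults that
matter, what the synthetic generators do and do not emulate, and the design
choices made where more than one convention exists.

## Chemical-shift-perturbation mapping

A 2D ¹H-¹⁵N correlation spectrum resolves one backbone-amide resonance per
non-proline residue. On ligand binding, residues at or near the interface
shift; the proton and nitrogen changes are combined as

    Δδ = sqrt( Δδ_H² + (α·Δδ_N)² )   [ppm]

where α rescales the ~5-fold wider ¹⁵N dispersion onto the ¹H scale. The
default α = 0.14 is the common backbone-amide convention; it is a
convention rather than a physical constant, so it is an explicit parameter
everywhere (`n_weight`).

Significance tiers are self-referential: a residue is *significant* when
Δδ > mean + 1σ and *strong* when Δδ > mean + 2σ, with mean and σ taken over
residues observed in both states only (population σ, ddof = 0 — this choice
reproduces the worked statistics used to validate the classifier).
Comparisons are strict, so a flat or single-residue profile flags nothing:
on degenerate input the method prefers false negatives to false positives.
Residues missing an amide H or N in either state (prolines, unassigned or
exchange-broadened peaks) are classed *unobserved* and excluded from the
statistics.

Hotspot clustering collects maximal runs of significant/strong residues.
One *unobserved* residue inside a run does not break it — proline gaps
would otherwise split biologically contiguous patches — but one observed,
sub-threshold residue does.

### File formats

Shift lists are TSV (columns `residue_number residue_type atom_name shift`,
`#` comments) or a minimal NMR-STAR v3 subset: only the `Atom_chem_shift`
loop (`Comp_index_ID`, `Comp_ID`, `Atom_ID`, `Val`) is interpreted, which
is sufficient to ingest a deposited backbone shift list.

## Heteronuclear NOE profiling

The steady-state ¹⁵N-{¹H} NOE ratio I_NOE/I_ref reports ps-ns backbone
mobility (~0.8 rigid core, low or negative for flexible linkers). Error
bars propagate a single global spectral-noise estimate,
σ_ratio = |ratio|·sqrt((σ/I_NOE)² + (σ/I_ref)²); per-peak noise estimates
are not modelled. Negative ratios are physical for flexible tails and are
never clipped. Region averages are arithmetic means over observed residues;
a region with no observed residues is reported as missing rather than
raised, so partial assignments do not abort a summary.

## ITC: models, conventions, fitting

### Single-site (Wiseman) model

The cell holds macromolecule at total concentration M, titrated with ligand
X from the syringe. After injection *i* the site occupancy θ solves the
mass-action quadratic

    θ² − θ·(1 + X/(N·M) + 1/(N·M·Ka)) + X/(N·M) = 0

and the cumulative heat content is Q_i = N·θ_i·M_i·V₀·ΔH. Each injection of
volume dV displaces cell liquid, so the measured heat is

    dQ_i = Q_i − Q_{i−1} + (dV_i/V₀)·(Q_i + Q_{i−1})/2

normalized per mole of injectant. **Dilution convention:** both M and the
cumulative X are scaled by (1 − dV/V₀) per injection — the standard
instrument-software convention. What matters for correctness is that the
simulator and the fitter share one convention exactly, which they do (they
call the same forward model). This convention legitimately shifts the
tight-binding plateau ~dV/2V₀ (≈0.5% here) off ΔH.

### Sequential-sites model

For k = 1..3 stepwise sites, species with j ligands bound have population
∝ β_j·[X]^j (β_j the product of stepwise constants K₁..K_j). The free
ligand concentration solves the mass balance by bracketed root-finding
(`brentq` on [0, X_total]) per injection — robust and exact to solver
tolerance. k = 1 reduces identically to the one-site model with N = 1. The
site count k is a user choice; nothing in the data model selects it
automatically.

### Fitting

`scipy.optimize.least_squares` over (N, log₁₀Ka, ΔH) with uniform weights
by default (optional per-point SDs), initialized from the isotherm itself:
ΔH from the first-plateau mean, N from the inflection molar ratio, Ka from
the slope at the inflection. Non-convergence is flagged, never silent; a
c-value (N·M₀·Ka) below 1 triggers a warning that N is poorly determined.
Parameter standard errors come from the Jacobian at the optimum. An
optional discard-first-injection flag exists and defaults to off.

Derived quantities use R = 1.9872 cal/(mol·K): Kd[μM] = 10⁶/Ka[M⁻¹],
ΔG = −RT·ln Ka (kcal/mol), ΔS = 1000·(ΔH − ΔG)/T (cal/(mol·K)); the unit
identities are asserted on every fit result in the test suite.

At the default study conditions (100 μM cell, 1 mM syringe, 20 × 2 μL,
0.1 kcal/mol heat noise) the Kd sampling distribution is visibly
right-skewed; recovery statistics therefore quote medians, while the
estimator-bias property (mean deviation from truth) is what the test suite
bounds at 5%.

## Ensemble and surface statistics

Superposition is the Kabsch SVD solution, the global least-squares minimum
over rigid transforms. **Backbone** means atoms named N, CA, C (carbonyl O
excluded). Ensemble spread is reported in both circulating conventions,
labelled in the output because they differ numerically (pairwise mean is
√2-fold larger than spread about the mean for Gaussian jitter): mean over
all model pairs of superposed RMSD (`pairwise_mean`, the default) and mean
RMSD to the iteratively refined mean structure (`to_mean_structure`).

The ordered core is found iteratively: fit all models on the retained
residues, compute each residue's mean positional spread about the ensemble
mean, drop residues above the cutoff (default 1.5 Å), refit; stop when the
retained set is stable or after 20 rounds. The output is the list of
maximal contiguous residue ranges.

RMSF is computed per atom about the time-mean position and averaged over
the selected atoms of each residue; frames are assumed already superposed
on the caller's chosen reference selection, so tumbling removal is an
explicit, visible step rather than a hidden default.

SASA is Shrake–Rupley with a deterministic Fibonacci-lattice point set
(default 960 points), so results are exactly reproducible — no random
sphere sampling. Van der Waals radii are a fixed documented table (C 1.70,
N 1.55, O 1.52, P 1.80, S 1.80, H 1.20 Å); hydrogens are included when
present, united-atom radii are not used. At 960 points the lattice
reproduces the analytic isolated-sphere area to <0.5% and dense-grid
integrations of overlapping-sphere systems to ~1%. Buried surface area is
BSA_r = SASA_r(component alone) − SASA_r(in complex), and the interface
area is half the summed BSA of both sides. Relative accessibility divides
residue SASA by the theoretical maxima of Tien et al. 2013 (PLoS ONE
8:e80635); values can exceed 1 for distorted termini and are not clipped.

## Interface geometry

Hydrogen bonds: d(D,A) ≤ 3.5 Å and, when an explicit hydrogen rides the
donor (any H within 1.25 Å in the same residue), D-H⋯A ≥ 120°; with no
hydrogens the call is distance-only. These are standard MD-analysis
defaults and are configurable; donor/acceptor typing comes from TSV
templates for the 20 amino acids and 4 ribonucleotides shipped as package
data. Occupancy is the exact fraction of frames in which a (donor atom,
acceptor atom) pair meets the criteria.

Stacking: centroids are unweighted centers of geometry; ring planes come
from an SVD fit. π-π requires centroid distance ≤ 5.5 Å, with interplanar
angle ≤ 30° the parallel family (lateral offset > 1.0 Å → displaced) and
≥ 60° T-shaped. Angles in (30°, 60°) satisfy neither definition and are
deliberately not reported — an ambiguous tilt should not silently inherit a
label. CH-π uses a 4.5 Å carbon-to-centroid cutoff, anion-π a 5.0 Å
phosphate-group-centroid cutoff. The lateral offset projects the
centroid-centroid vector onto the mean ring plane (normals sign-aligned
before averaging). All measured values are reported alongside the label so
a different convention can be re-applied downstream.

## RNA stem-loop logic

Hairpin-designed oligonucleotides are folded by zipping the terminal stem:
position k pairs with L+1−k while the bases are Watson–Crick (G·U optional,
off by default) and at least 3 unpaired bases remain; the first non-pairing
position ends the stem. No bulges, internal loops, or free-energy
minimization — this mirrors how such constructs are designed and keeps the
imino-count prediction exact: one protected imino per Watson–Crick pair
(U H3 or G H1), two per G·U wobble. Positions are 1-based. General
secondary-structure prediction is out of scope.

## Docking restraints

Active residues are those with significant or strong CSPs. Passive residues
approximate what docking servers derive automatically: relative SASA > 50%
with a heavy atom within 6.5 Å of an active residue's heavy atom, actives
excluded. The emitted text uses the ambiguous-distance-restraint dialect
(`assign (resid … and segid A) (… or …) 2.0 2.0 0.0`), i.e. an effective
distance of 2.0 Å with bounds 0.0–2.0; both the distance and the vicinity
radius are parameters. NOE restraint classes follow the conventional
separations: |i−j| = 0 intraresidual, 1 sequential, 1<|i−j|<5 medium-range,
>4 long-range; percentages are rounded half-up to two decimals to match
printed-table formatting.

## Synthetic generators

Every generator is bit-reproducible from its seed and returns its planted
truth, so no test infers truth from data. Defaults describe the study
system: a 97-residue domain numbered from 231, hotspot clusters at
262–267 and 270–275 (Δδ_H 0.20 ppm, Δδ_N 1.00 ppm) over Gaussian noise
(σ_H 0.01, σ_N 0.05 ppm); 20-model ensembles with a rigid core and
2 Å-jitter tails; 20-frame trajectories spanning 10 ns; isotherms at the
titration scheme above.

What they deliberately do **not** emulate: real chemical-shift physics
(base values are uniform draws from plausible amide ranges), correlated or
peak-dependent noise, exchange broadening, MD force-field physics
(hydrogen bonds toggle between idealized bonded/broken geometries), or
residue-template ring geometry (stacking fixtures are exact regular
hexagons, 1.39 Å bond length, chosen so centroids and normals have closed
forms). Passing tests therefore demonstrate correctness of the *analysis*
under known ground truth, not performance on experimental spectra.

## Problem sizes

The test suite and the acceptance script run at the sizes the analyses are
designed for: 100-replicate recovery studies for ITC and CSP sensitivity,
100 random toys for the hydrogen-bond brute-force comparison, 10⁵–10⁶-point
numerical oracles for surface areas, ensembles of 2–20 models. The full
suite completes in well under a minute on one core.

## Known limitations

- The CSP nitrogen weighting α and all geometric cutoffs are conventions;
  results near a threshold should be read with the reported raw values.
- The one-site fitter assumes heats are already dilution-corrected
  (`subtract_dilution` is a separate, explicit step).
- The passive-residue rule is an explicit approximation of docking-server
  defaults, not a reimplementation of any server's internal logic.
- PDB handling covers coordinates, chains, altloc A and multi-model files;
  mmCIF beyond what gemmi maps transparently, and MD-engine trajectory
  formats, are out of scope (frames arrive as multi-model PDB).
- Interface numbers that depend on a specific docked complex model
  (total interface areas, per-residue BSAs, bond redundancy counts) are
  only as good as the supplied coordinates; the package characterizes a
  given model, it does not produce one.
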