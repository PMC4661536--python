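# nmrbind

Tools for mapping how a protein domain recognizes an RNA hairpin, built
around the workflow used to characterize RRM (RNA recognition motif)
domains binding stem-loop RNAs in solution: NMR chemical-shift-perturbation
(CSP) mapping, isothermal titration calorimetry (ITC), NMR-ensemble
coordinate statistics, and geometric analysis of the docked protein-RNA
interface.

It is aimed at structural biologists and biophysicists who have titration
shift lists, ITC thermograms and multi-model coordinate files on disk and
want a scriptable, tested alternative to clicking through instrument and
visualization software.

## What it computes

**CSP mapping** (`nmrbind.csp`). For backbone amides observed free and
bound, the combined perturbation

    Δδ = sqrt( Δδ_H² + (α·Δδ_N)² ),   α = 0.14 by default

with significance tiers against the profile's own statistics: *significant*
above mean + 1σ, *strong* above mean + 2σ. Consecutive significant residues
form hotspot clusters (single unobserved gaps, e.g. prolines, do not break
a run).

**ITC** (`nmrbind.itc`). Forward simulation and weighted least-squares
fitting of the single-site Wiseman isotherm and the stepwise
sequential-sites model, with per-injection dilution bookkeeping, heats of
dilution subtraction, and the thermodynamic derivations
Kd = 1/Ka, ΔG = −RT·ln Ka, ΔS = (ΔH − ΔG)/T.

**Ensemble statistics** (`nmrbind.structure`). Multi-model PDB I/O, Kabsch
superposition, ensemble RMSD (mean pairwise or to the iterative mean
structure), automatic detection of the ordered core, per-residue RMSF,
Shrake–Rupley SASA on a deterministic Fibonacci lattice, buried surface
areas and relative accessibilities.

**Interface geometry** (`nmrbind.interface`). Hydrogen bonds by
distance/angle criteria with donor/acceptor templates for amino acids and
ribonucleotides, per-bond occupancy over trajectory frames, and π-π / CH-π
/ anion-π stacking with measured centroid distance, interplanar angle and
lateral offset.

**RNA stem-loop logic** (`nmrbind.rna`). Maximal terminal Watson–Crick stem
detection for hairpin-designed oligonucleotides, dot-bracket output, and
the predicted count of protected imino-proton resonances (one per
Watson–Crick pair, two per G·U wobble).

**Docking restraints** (`nmrbind.restraints`). NOE restraint statistics by
|i−j| class, and CSP-derived ambiguous interaction restraints (AIRs):
active residues from the significance tiers, passive residues from solvent
exposure near the active patch.

**Synthetic data** (`nmrbind.synthetic`). Seeded generators for every input
above — shift tables with planted hotspots, ensembles with ordered cores
and disordered tails, trajectories with prescribed hydrogen-bond
occupancies, idealized stacking geometries — each returning its ground
truth.

## Worked example

Fold the 25-mer hairpin used as the RNA ligand:

```sh
$ nmrbind stem --seq CGUAUCUUUAACUACUCAAGAUACG
pairs	8
loop	9-17 (9 nt)
imino_resonances	8
dot_bracket	((((((((.........))))))))
```

Eight terminal Watson–Crick pairs close a 9-nucleotide loop, predicting 8
imino resonances in a 1D ¹H spectrum — the hairpin is intact.

Simulate a titration at the measured binding parameters and fit it back:

```sh
$ nmrbind itc-sim --n 0.72 --dh -6.64 --kd-um 10 --cell-um 100 \
    --syr-um 1000 --noise-sd 0.1 --seed 1 --out isotherm.tsv
$ nmrbind itc-fit --isotherm isotherm.tsv
{
  "N": 0.7200347681703059,
  "Ka_per_M": 100303.62197961382,
  "Kd_uM": 9.969729709294493,
  "dH_kcal_per_mol": -6.6046951344696465,
  "dG_kcal_per_mol": -6.81958395581272,
  "dS_cal_per_mol_K": 0.7211034273257508,
  "converged": true,
  ...
}
```

With 0.1 kcal/mol of heat noise the fit recovers the stoichiometry (N ≈
0.72), affinity (Kd ≈ 10 μM) and enthalpy (ΔH ≈ −6.6 kcal/mol), and the
derived entropy term is small — binding is enthalpy-driven.

Generate a full synthetic bundle and map its planted CSP hotspots:

```sh
$ nmrbind simulate --seed 1 --outdir demo/
$ nmrbind csp --free demo/shifts_free.tsv --bound demo/shifts_bound.tsv \
    --out csp.tsv
mean_csp_ppm	0.03894
sd_csp_ppm	0.07726
significant	262,263,264,265,266,267,270,271,272,273,274,275
strong	262,263,264,265,266,267,270,271,272,273,274,275
clusters	262-267;270-275
```

The two planted hotspot clusters on the RNA-binding face are recovered
exactly.

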