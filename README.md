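# hydrolase-duo

Desk-scale, reproducible re-implementations of the computational analyses
used to characterize two-enzyme PET (polyethylene terephthalate)
depolymerization systems — a PETase that attacks the polymer and an
MHETase that hydrolyzes the soluble intermediate MHET to terephthalate and
ethylene glycol. The package is aimed at computational enzymologists and
bioinformaticians who want each analysis stage as a tested library function
rather than a one-off script, together with synthetic-data generators that
make every stage runnable and checkable on a laptop.

Four analysis stages, each with its own module and synthetic input
generator:

1. **Free-energy surfaces and rates** (`hydrolase_duo.fes`) —
   reconstruction of a 2D free-energy surface G(x, y) from umbrella-sampling
   windows by self-consistent WHAM,

   P(b) ∝ Σᵢ nᵢ(b) / Σᵢ Nᵢ·exp[(fᵢ − cᵢ(b))/k_BT],  fᵢ = −k_BT·ln Σ_b P(b)·exp[−cᵢ(b)/k_BT],

   minimum free-energy path (MFEP) extraction on the 8-connected grid
   (bottleneck-optimal search plus steepest-descent refinement), block
   bootstrap errors, and Eyring transition-state-theory rates
   k = κ·(k_BT/h)·exp(−ΔG‡/RT). The synthetic stage samples a double-well
   potential V = A·(x²−1)² + B·(y−sx)² with overdamped Langevin dynamics,
   so the planted barrier A is known ground truth.
2. **Enzyme kinetics** (`hydrolase_duo.kinetics`) — nonlinear least-squares
   fits of initial-velocity data to Michaelis–Menten,
   v = k_cat·E₀·S/(K_m + S), and the Haldane substrate-inhibition model,
   v = k_cat·E₀·S/(K_m + S + S²/K_k), with extra-sum-of-squares F-test model
   selection, AICc, case-resampling bootstrap confidence intervals, and
   initial-rate estimation from product timecourses.
3. **Family bioinformatics** (`hydrolase_duo.family`) — per-position
   conservation profiles (relative entropy in bits) referenced to a query
   sequence's numbering, cysteine/disulfide-position conservation,
   simplified Plan-7 profile HMMs for subfamily discrimination
   (FAE-like vs tannase-like), and neighbor-joining trees with
   column-resampling bootstrap support.
4. **Structure geometry** (`hydrolase_duo.structure`) — PDB reading/writing
   (via gemmi), disulfide detection (Sγ–Sγ ≤ 2.3 Å), Ser–His–Asp
   catalytic-triad distances, inter-residue minimum distances, and
   distance-trajectory statistics (mean ± sd, hydrogen-bond occupancy).

## Worked example

Run the whole pipeline on its synthetic demonstration inputs:

```bash
printf 'seed: 3\nfes_samples_per_window: 1500\nfamily_bootstrap: 30\n' > run.yaml
hydrolase-duo run --config run.yaml --out out
```

Selected numbers from `out/report.json` (seed 3):

```
fes.barrier_kcal_mol            9.97    # planted barrier was 10.0
fes.reaction_free_energy        0.02    # symmetric double well: ~0
kinetics.model                  MM_SI   # substrate inhibition detected
kinetics.kcat_per_s             28.2    # generating truth 27.6 (5% noise)
kinetics.km_uM                  23.7    # generating truth 23.17
kinetics.kk_uM                  291.9   # generating truth 307.30
family.reference_subfamily      A       # query classified to its own subfamily
structure.n_disulfides          5       # five planted Sγ–Sγ pairs found
structure.linkage_distance_A    2.9     # planted main-chain contact
```

The WHAM→MFEP chain recovered the planted 10 kcal/mol barrier to 0.03
kcal/mol; the substrate-inhibition fit recovered all three kinetic
constants within the noise; the geometry scans returned exactly the
planted features. Individual stages are available as subcommands, e.g.

```bash
hydrolase-duo fes rate --barrier 19.8
# k = 3.360e-02 s^-1 (dG‡ = 19.8 kcal/mol, T = 303.15 K, kappa = 1.0)
hydrolase-duo kinetics fit --table out/kinetics/velocities.tsv --model auto
hydrolase-duo structure disulfides --pdb out/structure/toy.pdb
```

or as library calls:

```python
from hydrolase_duo.fes import ReactionPath, two_step_summary

acyl = ReactionPath.from_values(13.9, -5.2, 0.17, 0.04)
deacyl = ReactionPath.from_values(19.8, +2.6, 0.10, 0.07)
s = two_step_summary(acyl, deacyl)
print(s.net_reaction_free_energy, s.rate_limiting, round(s.log10_rate_ratio, 2))
# -2.6 deacylation 4.25
```

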