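# Methods

This note documents the models behind each module, the defaults and why
they were chosen, the numerical details that matter for reproducing
results, and the limits of what the synthetic generators can show.

Units are fixed package-wide: energies in kcal/mol, lengths in Å, time
in s, substrate concentrations in µM, enzyme concentrations in nM,
temperatures in K. R = 1.987204×10⁻³ kcal/(mol·K); k_B and h at their
CODATA (2018, exact) values, giving k_BT/h = 6.317×10¹² s⁻¹ at the
default temperature of 303.15 K (30 °C, the assay temperature all rate
and kinetics defaults assume).

## Synthetic umbrella sampling

The model landscape is V(x, y) = A·(x²−1)² + B·(y−s·x)² on
[−2, 2]² — the simplest two-basin surface with a single saddle whose
height A is known exactly (minima at (±1, ±s) with V = 0, saddle at the
origin with V = A). Defaults A = 10 kcal/mol, B = 5 kcal/mol/Å²,
s = 0.5 plant a barrier comparable to an enzymatic chemical step and a
mildly tilted transverse valley so the minimum-energy path is genuinely
two-dimensional. A pure harmonic form (½B(x²+y²)) is available as an
oracle whose reconstructed surface must be quadratic with known
curvature.

Windows are sampled with first-order Euler–Maruyama overdamped Langevin
steps on V plus the harmonic restraint. The mobility is set to 1 (only
µ·Δt matters for the stationary density, so the time unit is
arbitrary). The default step keeps µ·k·Δt = 0.02 against the local
curvature bound at the window center (Gershgorin bound on the Hessian)
plus the restraint constant; the first-order discretization bias in
sampled variances is then ≈ µkΔt/2 = 1%, well inside the 5% tolerance
the Boltzmann-fidelity tests use. For nearly flat landscapes the step
is instead capped so a single diffusive move is ≤ 5% of the domain.
Trajectories reflect off the domain boundary, which makes the unbiased
flat-potential density exactly uniform. Burn-in is 10% of the retained
length; a thinning stride (default 10 in the batch sampler) keeps
retained samples only weakly autocorrelated. Divergence (a single step
larger than the domain) raises an integration error naming the step
size.

The default window layout tiles x ∈ [−1.3, 1.3] × y ∈ [−0.8, 0.8] with
13×9 centers and force constants of 60 kcal/mol/Å² on both coordinates.
The restraint must exceed |V_xx| = 4A = 40 kcal/mol/Å² at the saddle,
where the landscape curvature is negative, or saddle-region windows are
unconfined; 60 gives biased widths of ~0.1 Å that overlap between
neighboring centers. At the default 8000 samples per window the full
set is 936 000 samples and the planted barrier is recovered to
within ±0.1 kcal/mol in practice (the acceptance bound is ±0.3).

## WHAM and the free-energy surface

The estimator is standard self-consistent 2D WHAM on a histogram grid
(default 50×50 over the sampled extent): iterate the coupled equations
for the bin probabilities and window shifts until the sup-norm change
of the shifts is below 10⁻⁷ kcal/mol (cap 10⁵ iterations; exceeding it
raises an error carrying the last residual). Exponentials are taken
directly in float64 — window shifts here stay far from overflow — with
one matrix product per iteration. The surface is −k_BT·ln P, zeroed at
its sampled minimum. Bins with fewer than 5 total samples are masked,
never interpolated; a disconnected sampled region triggers a warning
and a flag. A histogram-free MBAR-style estimator was considered and
not included in v1: at these problem sizes the histogram estimator is
exact enough that the binning term is invisible next to sampling noise.

The quick per-bin standard error is counting noise k_BT/√n_eff, where
each window's contribution is discounted by its integrated
autocorrelation time (initial-positive-sequence estimator, capped at a
tenth of the series length). This keeps the "flat surface within 3σ"
check honest for correlated Brownian samples. Serious error bars come
from the moving-block bootstrap (default 50 replicates, block length =
series length / 20): each replicate rebuilds every window from
contiguous blocks, re-runs WHAM on the reference grid and re-extracts
the path; reported errors are standard deviations over replicates.

## Minimum free-energy path

On a discrete surface the MFEP is defined in two stages. First a
Dijkstra-style bottleneck search over the 8-connected sampled bins
finds the path minimizing the maximum free energy en route; ties break
toward the lower running sum of free energy, then lexicographic bin
order, so the result is deterministic. The highest bin on that path is
the saddle. Second, steepest descent (lowest 8-neighbor) from the bins
flanking the saddle relaxes each side toward its basin; if a descent
ends in a basin other than the requested one the bottleneck segment is
kept for that side. ΔG‡ = G(saddle) − G(reactant),
ΔG_reaction = G(product) − G(reactant). The bottleneck stage is
verified against exhaustive path enumeration on tiny grids and against
an independent threshold/flood-fill oracle up to 6×6.

Automatic basin pairing (`select_reaction_basins`) takes the global
minimum plus the lowest basin at least 25% of the grid diagonal away
from it — sampling noise can split one physical well into several
nearby local minima, and the nearest-two rule would pair those.

## Rates and the two-step mechanism

Rates use the Eyring form k = κ·(k_BT/h)·exp(−ΔG‡/RT) with κ = 1 by
default; a negative barrier is capped at the prefactor with a warning.
Barrier errors propagate to first order, σ_k = k·σ_ΔG‡/RT. For a
two-step serine-hydrolase mechanism the summary reports the net
reaction free energy (sum of steps, errors in quadrature), the
rate-limiting step (larger barrier; exact ties labelled "tie"), and
log₁₀(k_fast/k_slow) = (ΔG‡_slow − ΔG‡_fast)/(RT·ln 10). Feeding the
published step energetics (13.9/−5.2 and 19.8/+2.6 kcal/mol) through
this arithmetic yields −2.6 ± 0.08 kcal/mol net and a ratio of 4.25
orders of magnitude. Note that the Eyring formula applied to the
rounded printed barriers gives ≈6.0×10² and ≈3.4×10⁻² s⁻¹; published
rate values for the same barriers were evidently computed from
unrounded inputs, so the order-of-magnitude ratio — not the absolute
rate — is the quantity this package treats as reproducible.

## Kinetics

The substrate-inhibition form is the single-site Haldane model
v = k_cat·E₀·S/(K_m + S + S²/K_k), the standard model for
ferulic-acid-esterase-like substrate inhibition; K_k → ∞ recovers
Michaelis–Menten, so the models are nested. Fits are unweighted
nonlinear least squares on velocities (optional 1/v²-style weighting
was considered and left out of v1 since the data the defaults emulate
carry relative noise of a few percent at all levels). Initialization:
k_cat₀ from the maximum observed velocity, K_m₀ as the lowest S at
half-maximum, K_k₀ = 10·max(S); parameters are bounded positive, and a
fitted K_k at the 10⁹ µM bound is reported as ∞ with an
`effectively_mm` flag. Identifiability: if the velocity maximum sits at
the largest tested S, no decline was observed and K_k carries a
`kk_unidentifiable` flag. Model choice is the extra-sum-of-squares
F-test at α = 0.05 with AICc reported alongside; an MM fit whose RSS is
at floating-point noise always selects MM regardless of RSS ratios.
Confidence intervals are case-resampling percentile bootstrap (default
500 replicates); K_k draws that escape to the bound make the upper CI
limit unbounded. Initial rates from timecourses use the least-squares
slope over points below 10% substrate conversion divided by E₀
(nM → µM). Velocities are accepted per-enzyme (s⁻¹) or as µM/s with
E₀; all reports are per-enzyme, which makes the constants invariant
under joint rescaling of E₀ and velocities (tested).

The synthetic generator's noise is multiplicative Gaussian at a stated
CV (HPLC-style relative error), default 5%; additive noise is an
option. The default truths are the three characterized enzymes' printed
constants; where an inset constant is not printed (the homologs' k_cat
and K_k), values were chosen once to match the described qualitative
behavior (comparable maximal rate, visibly weaker inhibition) and are
not reported as recovered quantities.

## Family analysis

All per-position outputs are numbered on the ungapped reference row
(1-based). Identity to the reference counts matching positions over
columns where at least one of the pair is ungapped (gap–gap columns are
dropped from the denominator); the percent-identity convention for
published pairwise values is typically unstated, so identities here are
internally consistent rather than tool-exact. Conservation is the
relative entropy of the column's non-gap residue distribution to a
background (pooled family frequencies by default, uniform available),
clipped to [0, log₂20] bits, with the modal residue and its frequency
reported alongside as the plainer score; a column empty outside the
reference yields a missing score, never zero.

The profile HMM is a simplified Plan-7 (match/insert/delete, global
mode). Match states are columns with ≤ 50% gaps; match emissions are
(counts + pseudocount·background)/(n + pseudocount) with a
Laplace-floored background; insert states emit the background;
transitions come from the observed state paths with add-one smoothing.
Scores are forward log-odds in bits against a null model that shares
the transition structure and emits the background everywhere — this
null makes a background-emission model score exactly zero and cancels
length and gap-structure effects, so subfamily comparisons reduce to
emission differences. Viterbi scores use the same null and can never
exceed the forward score. Absolute scores from production HMM software
are not comparable; only the sign and size of the margin between two
subfamily models is meaningful here, and the package's discrimination
claim is stated as held-out classification accuracy (≥95% at high
divergence, degrading monotonically as divergence vanishes).

Trees are canonical Saitou–Nei neighbor joining on 1 − fractional
identity distances, with Q-criterion ties broken lexicographically;
negative branch-length estimates are clamped to zero with the deficit
moved to the sister branch so the joined pair distance is preserved. NJ
is exact on additive matrices, which is the correctness oracle (plus a
cross-check against scikit-bio's implementation on random matrices).
Bootstrap support is column resampling: the support of an internal
edge is the fraction of replicate trees containing its leaf
bipartition.

## Structure geometry

PDB I/O goes through gemmi. One atom is kept per (chain, residue, atom
name): highest occupancy wins, ties resolve toward altloc 'A'.
Hydrogens are kept but flagged and excluded from geometry scans; waters
are tagged. Residues are identified by author numbering, matching how
catalytic residues are cited. Disulfides are CYS Sγ pairs within
2.3 Å (covalent S–S ≈ 2.05 Å), the boundary applied as ≤; each
cysteine joins at most one bond, conflicts resolved greedily by
ascending distance. Triad geometry reports Ser Oγ–His Nε2 and His
Nδ1–Asp Oδ (nearer of Oδ1/Oδ2), each flagged against a 3.5 Å
heavy-atom hydrogen-bond cutoff. Minimum inter-residue distances
support all-heavy, main-chain (N, CA, C, O, OXT) and side-chain
selections and report the achieving atom pair, since "main-chain
contact" citations rarely name the atoms. Distance series report mean,
sample standard deviation (n−1) and occupancy (fraction of frames ≤
threshold). All distance operations are invariant under rigid motions
(tested with random rotations + translations).

The toy-structure builder places minimal residues in clusters 25 Å
apart so the only sub-cutoff contacts are the planted ones; planted
geometry is exact by construction, which is what makes the geometry
scans falsifiable. The published crystal structures (PDB 6QZ1–6QZ4)
are not bundled with the package; the geometry operations accept any
PDB file, and the bundled checks run on synthetic structures carrying
the same feature set (five disulfides, Ser/His/Asp triad, a 2.9 Å
main-chain lid linkage).

## What the synthetic data do and do not show

The generators reproduce the *statistical structure* each estimator
assumes: Boltzmann-distributed biased samples on a known landscape,
velocity curves from the exact rate law with relative noise, families
with position-wise independent substitutions and a planted two-block
structure, structures with exact planted geometry. They do not emulate
QM/MM energetics, correlated MD dynamics beyond the Langevin
autocorrelation, phylogenetic site-rate heterogeneity or indel
evolution, or crystallographic disorder. Passing tests therefore
demonstrate that the estimators are correct and well-calibrated under
their own assumptions at desk scale — not that those assumptions hold
for any particular experimental dataset.

## Problem sizes

Defaults were chosen so the full test suite runs in about a minute and
the acceptance script in well under one: 117 umbrella windows × 8000
samples (≈ 9.4×10⁶ integrator steps with stride 10), 50×50 WHAM grids,
14-point substrate grids, families of 30–300 sequences × 30–60 columns,
100 bootstrap replicates for trees and 500 for kinetics CIs.
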