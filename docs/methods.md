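# Methods

This note documents the models, estimators, numerical policies, and
synthetic-data conditions behind `gatefep`, and what the tests do and do
not establish.

## Units and constants

Energies are kcal/mol internally (kJ/mol inputs divided by exactly 4.184
on ingestion), lengths Å (GRO nm × 10), temperatures K with a 310 K
default, angles degrees at API boundaries. R = 0.0019872041 kcal/(mol·K);
e²/(4πε₀) = 332.06371 kcal·Å/(mol·e²); V° = 1660 Å³ (1 M standard state).
Umbrella bias constants are accepted in the MD-engine convention
kJ/mol/nm² and converted (factor 1/418.4) to kcal/mol/Å².

## Gate collective variable

ξ is the Euclidean distance between the *unweighted* means of the Cα
positions of two inclusive residue ranges (defaults 113–117 and 235–239;
both are configurable — one published figure caption cites 235–237 for
the second group, but the methods definition 235–239 is adopted). The CV
is invariant under rigid-body transforms and within-group atom order.
Frame assignment for window seeding picks the trace frame minimizing
|ξ − center|, earliest frame on ties. The window grid requires the
spacing to divide the range exactly (no silent truncation); (13, 19,
0.25 Å) gives the standard 25 windows.

## Model surfaces and the Metropolis sampler

`double_well(offset)` is a quartic-plus-linear polynomial
h·((x−m)²/w²−1)² + t·(x−m) with m = 15.85 Å, w = 1.65 Å, and barrier
parameter h = 1.5 kcal/mol, chosen to mimic the shallow occluded-vs-open
landscape: minima near 14.4 and 17.6 Å separated by a gentle hump. The
tilt t is solved by Brent root-finding so that the *exact* well-depth
difference equals −`offset` (default 2.2 kcal/mol, the open basin lower).
Beyond the wells the quartic walls are continued linearly (C¹) once their
slope reaches 2 kcal/mol/Å, so that a 1000 kJ/mol/nm² umbrella bias can
hold windows on the flanks; without the cap the quartic wall gradient
exceeds what that bias can restrain and edge windows collapse inward.
The exact minima locations and depth offset are stored on the object;
the Boltzmann basin free-energy difference (quadrature of exp(−U/RT)
per basin, split at the barrier top) is also available and is the
conceptually distinct "population" counterpart of the depth offset.

`sample_biased` runs 32 independent Metropolis walkers with Gaussian
proposals, rejecting moves outside the domain. The proposal width is
tuned during burn-in (default max(1000, 0.1·n/chains) steps per chain)
toward 30–50% acceptance in multiplicative steps. Samples from all
chains are interleaved; streams are bit-reproducible for a fixed seed
(`numpy` PCG64, per-window seeds spawned from a `SeedSequence`).
Correctness is checked against Gaussian closed forms (mean, variance
RT/K) at n = 10⁵.

## WHAM

Self-consistent iteration of the standard equations on a shared uniform
bin grid (default 200 bins spanning the window centers), entirely in log
space with max-shifted log-sum-exp. Convergence: max |ΔF_j| < 10⁻⁷
kcal/mol, max 10⁵ iterations. Every bin in the analysis range must hold
at least one sample, otherwise an `AnalysisError` suggests fewer bins.
G(ξ) = −RT ln P(ξ) is anchored at its global minimum in *every*
solution, including the trailing-fraction sub-solutions, so the reported
per-bin SD over the last-50/40/30/20/10% solutions measures shape
variation rather than anchor drift. Bins empty in any sub-fraction get
NaN uncertainty, never zero. A binless MBAR reweighting of the pooled
samples (`mbar_pmf`) serves as an independent cross-check in the tests;
it is not the product path.

`basin_difference` returns min_B G − min_A G (negative: B lower) and
requires each interval's minimum to be interior — a monotonic stretch
raises an error rather than reporting an endpoint as a "basin".

## MBAR, TI, and cycles

MBAR solves f_i = −ln Σ_n exp(−u_i(x_n))/Σ_k N_k exp(f_k − u_kn),
gauge-fixed f_0 = 0, by self-consistent iteration switching to
Newton–Raphson below a residual of 10⁻², to a tolerance of 10⁻¹² on f.
States with N_k = 0 are perturbation targets evaluated after
convergence. Uncertainties come from the asymptotic covariance
Θ = VS(I − SVᵀNVS)⁺SVᵀ of the weight matrix W_ni = exp(f_i − u_in)/D_n
(economy SVD, pseudo-inverse). No equilibration detection or
autocorrelation subsampling is applied: the estimator consumes raw
samples, and sample independence is the caller's responsibility (the
synthetic generators draw i.i.d. samples; MD users should decorrelate
upstream). TI is trapezoidal with SE propagation under the trapezoid
weights. Cycle assembly is a signed sum with quadrature errors.

The λ registries hold the published protocols: binding
complex = 10 restraint (0.01…1.0) + 11 charge (Δλ = 0.1) + 15 vdW
(0.05…1.0) = 36 windows; water = 26; protonation = 11 charge + 5
bonded+vdW (Δλ = 0.25) = 16. The λ = 0 end of the restraint/vdW legs
coincides with the previous leg's endpoint and is not a separately
sampled window, which is why those legs start above zero.

## Boresch restraint

The release term uses the rigid-rotor closed form (see README). It is
exact in the stiff-restraint limit; the implementation warns when
fluctuations √(RT/K) become comparable to the geometric scales. The term
depends on r₀, the two angle equilibria and the six force constants only
— never on the dihedral equilibria — and the tests verify it against a
separable 6D quadrature of the restrained configurational integral to
0.05 kcal/mol. Default fixture constants are 10 kcal/mol/Å² and
100 kcal/mol/rad²; for real runs they are required inputs, not defaults.
Sign bookkeeping is centralized in `assemble_abfe`
(ΔG_bind = ΔG_water − ΣΔG_complex − ΔG_release, all legs forward);
estimators never return pre-negated values.

Restraint equilibrium values from unbiased traces use the arithmetic
mean for the distance and the circular mean (atan2 of mean sine/cosine,
mapped to (−180°, 180°]) for angles and dihedrals; a near-zero resultant
length makes the circular mean undefined and raises.

## Finite-size correction and pseudo-pKa

For a net charge q in a cubic box of edge L:

    ΔG_cor = −ξ_LS q²/(8πε₀ε_s L) − γ_s q N_s/(6ε₀L³)
             + (2π/3)·k_C·q²·(R²/L³)·(1 − 1/ε_s)

with ξ_LS = −2.837297, ε_s = 78.4, γ_s = 0.764 e·Å² and a spherical
cavity radius R (default 2 Å). The third term is a closed-form
homogeneous-dielectric spherical-cavity stand-in for the residual
integrated potential; a numerical Poisson evaluation with the real
solute shape and heterogeneous dielectric would be more faithful but is
deliberately out of scope. The discrete-solvent term treats the solvent
count N_s as a fixed parameter (default 1000) so it decays as 1/L³; in a
constant-density box N_s grows with L³ and this term is instead nearly
size-independent — a known simplification of the model used here. The
synthetic box-size generator plants exactly this model, so the
correction inverts the artifact by construction; that inverse
consistency tests the bookkeeping, not the physical accuracy of the
correction. The 8-box (30–100 Å) × 3-replicate protocol with replicate
scatter of 0.005 kcal/mol SD is the emulated study condition; the
box-independence check reports the max pairwise spread and the 24-trial
mean against a 0.05 kcal/mol tolerance.

pKa = pH_ref − ΔG_prot/(RT ln 10) with pH_ref = 7.0, the unique constant
reproducing all four published (ΔG, pKa) pairs at 310 K to ±0.02 pK
(verified as a test, since the conversion constant is reconstructed, not
printed); the slope is −0.705 pK per kcal/mol at 310 K. No standard-state
or entropy corrections are applied — hence "pseudo".

## Dihedral refit

RB convention ψ = φ − 180°, V = Σ C_n (cos ψ)ⁿ; "three-term" = C₀, C₁,
C₂ free. The fit is linear weighted least squares (1/SE² weights when
SEs are present), with rank checking; the covariance is (XᵀWX)⁻¹
(residual-scaled for uniform weights). A converter to the plain cosine
convention (a_n = (−1)ⁿ C_n) is provided because scan comparisons are
convention-sensitive. `rescan_check` removes the least-squares constant
offset before comparing, and `syn_anti_gap` = V(0°) − V(180°) = −2(C₁ +
C₃ + C₅) exposes the rotamer balance the refit exists to fix.

## Problem sizes and what the tests show

Recovery tests run at the protocol scales: 25 windows × 5×10⁴ samples
for the basin-difference readout, 5×10⁴ samples/state for two-state
MBAR, 100 replicate fits for the dihedral Monte-Carlo calibration; unit
tests use smaller draws. The synthetic layer draws independent (or
short-memory Metropolis) samples from exactly the assumed models — 1D
surfaces, Gaussian states, Gaussian noise. Passing tests therefore
demonstrate estimator correctness and calibrated uncertainties under
those assumptions; they do not speak to force-field accuracy, sampling
convergence of real MD, autocorrelation handling, or multidimensional
gating pathways, none of which the synthetic layer emulates.

## Known limitations

- WHAM is 1D only; no Bayesian/MBAR replacement on the product path.
- No trajectory formats: the pipeline consumes extracted time series and
  static single-frame coordinates (no PBC minimum-image handling).
- The finite-size model's spherical-cavity and fixed-N_s simplifications
  (above).
- Boresch force constants and equilibration protocol for real systems
  are user inputs; no automatic anchor selection.
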