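# Methods

This note documents the model, the estimators, the numerical choices, and
what the validation suite does and does not demonstrate. Units throughout:
Å, kcal/mol, Kelvin, k<sub>B</sub> = 0.0019872041 kcal/(mol·K).

## The thermodynamic cycle

We estimate the standard-state binding free energy

ΔG = −k<sub>B</sub>T ln [ Z<sub>PL</sub> / (Z<sub>P</sub> Z<sub>L</sub> V° Ω) ],

with V° = 1660 Å³ (1 M standard state) and Ω the rotational volume of the
ligand's rigid-body orientation under the measure described below. The
cycle has three legs:

- **0 → r**: add the restraint U<sub>ζ</sub> to the decoupled system.
  Because U<sub>ζ</sub> is Gaussian × Bingham, the partition factor is
  analytic: ΔG(0→r) = −k<sub>B</sub>T [ln(Z<sub>t</sub>/V°) +
  ln(Z<sub>q</sub>/Ω)] with Z<sub>t</sub> = (2π)^{3/2}|Σ|^{1/2} and
  Z<sub>q</sub> the Bingham normalizer.
- **r → rc**: restrict the restrained decoupled ensemble to its clash-free
  subset. Since the two states differ only in their domain of integration,
  ΔG(r→rc) = −k<sub>B</sub>T ln α where α is the probability that a sample
  of the restrained decoupled ensemble is clash-free, estimated from the
  combinatorial filter.
- **rc → 1**: a single two-state MBAR estimate between the clash-free
  decoupled ensemble and the coupled complex ensemble.

**Bookkeeping of the restraint.** The reduced potentials fed to MBAR are
u<sub>rc</sub> = β[U<sub>P</sub>(x<sub>P</sub>) + U<sub>L</sub>(x<sub>L</sub>)
+ U<sub>ζ</sub>(ζ(x))] (with +∞ outside the clash-free region) and
u<sub>1</sub> = βU<sub>PL</sub>(x) — the coupled end state carries **no**
restraint. With this bookkeeping the cycle telescopes exactly:

−k<sub>B</sub>T[ln(Z<sub>ζ</sub>/(V°Ω)) + ln α +
ln(Z<sub>1</sub>/(αZ<sub>P</sub>Z<sub>L</sub>Z<sub>ζ</sub>))] =
−k<sub>B</sub>T ln(Z<sub>PL</sub>/(Z<sub>P</sub>Z<sub>L</sub>V°Ω)).

Had the restraint been kept in the coupled state, the total would instead be
the free energy of binding to the *restrained* complex, off by
−k<sub>B</sub>T ln⟨e^{−βU_ζ}⟩<sub>PL</sub>, which is not small for a
restraint fit tightly to the bound ensemble. The choice is validated by the
end-to-end toy tests, which recover independently computed ΔG values to
well within their standard errors; the restraint parameters themselves
cancel between the release leg and the sampled ensembles (verified by the
Σ-doubling robustness test).

Complex-trajectory frames whose ζ falls outside the fitted mode are kept:
the restraint energy reweights them, and MBAR handles the tails. Complex
frames that violate a clash cutoff (possible for transient tight contacts)
get u<sub>rc</sub> = +∞, i.e. zero weight in the conditional state, which
is exactly what the conditional partition function prescribes.

## Rigid-body coordinate and measures

ζ = (t, q) is defined against one arbitrary reference complex frame: the
current frame's pocket Cα atoms are Kabsch-superposed onto the reference
pocket, then the minimal-RMSD rigid transform carrying the reference ligand
onto the aligned current ligand is taken, minimizing over all
element-preserving graph automorphisms of the ligand (molecular symmetry).
Rotations act about the reference-ligand centroid so t and q decouple.
Quaternions are scalar-first, unit, canonicalized to the q<sub>w</sub> ≥ 0
hemisphere (ties: first nonzero component positive).

All quaternion integrals run over the full sphere S³ with surface measure
(total 2π²); densities are antipodally symmetric, and the unrestrained
rotational reference is the uniform density on S³, so the double-cover
factor of two cancels identically between Z<sub>q</sub> and Ω = 2π². A
ligand with fewer than three non-collinear atoms has no resolvable
rotation; the restraint is then translational only and the rotational
factor is absent from both the density and the release term, keeping the
cycle consistent.

Decoupled poses are generated per receptor frame in that frame's own
coordinate system by inverting the frame's pocket alignment, so the
restraint is defined relative to the pocket rather than the lab frame.
Ligand-only conformers are symmetry-aware superposed onto the reference
ligand pose before restraint transforms are applied. For rigid or
single-atom guests this change of coordinates is exact; for flexible
ligands the least-squares alignment is the standard approximation and its
conformation-dependent Jacobian is neglected (see Limitations).

## Restraint model

- **Mode selection**: mean-shift in the 7-dimensional embedding [t, q]
  (3-dimensional for non-rotational ligands). The bandwidth default is the
  0.3 quantile of pairwise distances on a ≤500-point subsample (sklearn's
  `estimate_bandwidth`). A KDE-style bandwidth (Scott) was tried first and
  rejected: it shrinks with n and at 10⁴ samples fragmented a unimodal ζ
  distribution into micro-clusters, fitting the restraint from ~2% of the
  data and inflating run-to-run variance beyond the reported standard
  error. Mean-shift iterations run on at most 1500 evenly spaced samples
  (the algorithm is quadratic in n); every sample is then assigned to its
  nearest discovered mode, so membership covers the full data set.
- **Translation factor**: sample mean and covariance of member
  translations; covariance eigenvalues floored at 10⁻⁴ Å² because rigid
  poses in short trajectories can collapse Σ.
- **Rotation factor**: eigendecomposition of the antipodally symmetric
  quaternion scatter E[qqᵀ]; principal axes M, concentrations Z by
  maximum-likelihood inversion of the scatter eigenvalues (bounded least
  squares on the moment equations to 10⁻⁸, concentrations clamped at
  −200). Gauge: max(Z) = 0, making the mode energy exactly zero.
- **Normalizer**: the Bingham constant over S³ is evaluated by adaptive
  tensor Gauss–Legendre quadrature in hyperspherical angles, doubling the
  order until the relative change is below 10⁻⁹ (well inside the 10⁻⁶
  contract); cross-checked against 10⁷-point Monte Carlo in the tests.
- **Sampling**: translations are exact multivariate-normal draws;
  quaternions use rejection sampling with the angular-central-Gaussian
  envelope (envelope parameter solving Σᵢ 1/(b+2aᵢ) = 1). An acceptance
  rate below 10⁻³ raises a concentration-overflow error. A χ² histogram
  test validates the sampler against the density.

## Clash filter

Per-pair cutoffs come from Lorentz–Berthelot combination (arithmetic σ,
geometric ε) and the closed-form repulsive-branch root of
4ε[(σ/d)¹² − (σ/d)⁶] = E: with y = (σ/d)⁶, y = (1+√(1+E/ε))/2, so
d = σ y^{−1/6} ≤ 2^{1/6}σ. The default E = 2 kcal/mol. Pairs with ε = 0
have no finite root and are exempt (c<sub>ij</sub> = 0); hydrogens with
ε > 0 are treated like every other atom. Intra-receptor and intra-ligand
contacts are never retested — those frames are already Boltzmann samples of
their own potentials, and the conditional state restricts only
receptor–ligand pairs.

The pose budget is N<sub>ζ</sub> = max(1, ⌊N<sub>target</sub>/(N<sub>P</sub>
N<sub>L</sub>)⌋) with N<sub>target</sub> defaulting to 10⁹ (the production
protocol); the validation suite uses 4×10⁵ with N<sub>P</sub> = 200 receptor
frames and N<sub>L</sub> = 50 conformers, at which the binomial
delta-method error on ln α is negligible against the other legs. Each
receptor frame gets one KD-tree; ligand atoms are queried at the maximum
cutoff radius and only candidate pairs are checked exactly, streaming in
batches with bounded memory. Equivalence with the brute-force O(P·L)
double loop is asserted on random instances, and the hard-sphere geometry
(point receptor, uniform box poses) reproduces 1 − (4/3)πc³/V and the
corresponding exclusion free energy analytically.

α = 0 is a structured no-overlap failure (the receptor ensemble leaves no
room for the ligand, e.g. a binding site that closed in the apo
simulation); it raises rather than returning a number, and multi-pose runs
exclude such poses explicitly instead of imputing them.

## Correlated-data reduction

The statistical inefficiency g = 1 + 2Σ(1 − t/N)C(t) uses an FFT
autocorrelation truncated at its first non-positive value. Equilibration is
detected by maximizing (N − t₀)/g(t₀) over a geometric grid of candidate
burn-in points with a floor of `min_burn_in` frames (default 50, i.e.
0.1 ns at 2 ps spacing); runs pooled from several files are reduced
independently before pooling. Thinning uses the float stride g (keeping
~N/g frames) rather than ⌈g⌉, which would halve the data when g barely
exceeds one. A constant observable has undefined autocorrelation and is
assigned g = 1 (keep everything). The default observable is the backend
total potential energy; flat-energy subsystems (rigid cages,
noninteracting guests) fall back to the first principal component of the
coordinates.

## Free-energy estimation

The two-state MBAR problem is solved by minimizing the convex MBAR
objective (L-BFGS with analytic gradient) followed by self-consistent
polish to 10⁻¹². +∞ reduced potentials are supported as hard walls. The
standard error is the maximum-likelihood (Bennett) asymptotic variance
[Σₙ aₙ(1−aₙ)]⁻¹ − n₀⁻¹ − n₁⁻¹ on the logistic weights aₙ; it was checked
against the empirical spread of repeated estimates. An algorithmically
independent Bennett-acceptance-ratio root finder (scalar bracketing on the
pooled self-consistency equation) agrees with the MBAR optimum to 10⁻⁶ and
serves as the dual route in the tests. The overlap diagnostic is
1 − λ₂ of the MBAR overlap matrix WᵀW·diag(N) (1 for identical states, 0
for disjoint ones); values below 0.01 attach a warning to the report
rather than failing the run, since a low-overlap estimate is still the
best available number and the user must see why it is fragile.

Subsampling to N<sub>s</sub> (default 5000 per state) happens *before*
energy evaluation, because backend calls dominate cost. Per-leg errors
combine in quadrature: the release leg is analytic (zero error), the
filter leg binomial, the MBAR leg asymptotic. Poses combine by
log-sum-exp Boltzmann weighting. The MM/GBSA baseline is the
single-trajectory mean of U<sub>PL</sub> − U<sub>P</sub> − U<sub>L</sub>
over complex frames with components cut from each frame, with no
conformational-entropy correction. Benchmark metrics (RMSE, Pearson,
Spearman) carry percentile-bootstrap 95% CIs over paired resamples
(default 1000).

## Toy systems: what they show and what they do not

The four presets are built so that every pipeline stage has nontrivial
work while ΔG is computable independently by deterministic quadrature
(relative tolerance 10⁻⁶, receptor internal modes marginalized in closed
form, ≤6 coupled degrees of freedom):

| preset | guest | site | exercises |
|---|---|---|---|
| `pure_harmonic` | 1 atom | harmonic (k = 2, depth 5) | soft receptor decorrelation, restraint fit, MBAR |
| `harmonic_lj` | 1 LJ atom | harmonic (k = 0.5) in a rigid LJ cage (σ = 3.2, ε = 0.15) | clash filter (α ≈ 0.94), Metropolis sampling, anharmonic MBAR |
| `double_well` | 1 atom | tilted quartic double well (a = 2, b = 1.1, tilt 0.5) | bimodal mode selection, reweighting across modes |
| `rigid_rotor` | rigid 3-atom triangle | harmonic + orientation coupling κ(1 − û·ẑ), κ = 2 | Bingham fit/sampling/normalizer end to end |

Boltzmann sampling is exact (independent draws) wherever the marginal is
Gaussian or separable; the LJ-coupled complex uses random-walk Metropolis
with automatic step tuning to ~40% acceptance and fixed thinning, checked
against importance-weighted uniform draws. The validation suite runs 10⁴
frames per ensemble and 4×10⁵ filter pairs per system, recovering the
quadrature references within three standard errors with se well below
0.3 kcal/mol, in seconds to tens of seconds per system on one core.

What passing these tests does **not** show about real systems: the toys
have no internal ligand flexibility (so the alignment Jacobian
approximation is untested beyond rigid bodies), no implicit-solvent model
(the backend contract carries it for real runs), pocket geometries that
never reorganize on binding, and exactly Boltzmann-distributed inputs
(real MD adds integrator and force-field error before this method ever
runs). The toys validate the estimator, not the energy model.

The MM/GBSA contrast is reproduced in controlled form: for a harmonic
site, the single-trajectory interaction energy exceeds the exact ΔG by
exactly (3/2)k<sub>B</sub>T + k<sub>B</sub>T ln(Z<sub>t</sub>/V°) — the
configurational/standard-state entropy it neglects. The tests assert this
closed form across a stiffness grid. Note the sign structure: the
deviation vanishes at a *soft*, entropy-neutral stiffness
(k ≈ 0.072 kcal/mol/Å² at 300 K) and grows for stiff traps, where MM/GBSA
overbinds by several kcal/mol; "entropy-free" in the rigid-trap intuition
does not survive the standard-state volume term.

## Other numerical choices and degenerate inputs

- Kabsch uses SVD with the determinant correction (reflections excluded);
  collinear point sets raise a degenerate-geometry error.
- Symmetry enumeration caps at 10⁴ automorphisms with a truncation flag;
  RMSD ties between permutations break to the lexicographically lowest.
- All randomness flows from one config seed through CRC-derived named
  substreams; reports are byte-identical across runs up to the timing
  block. Seeds stay below 2³¹.
- Reservoir subsampling caps the retained clash-free samples (default
  2×10⁴) before the N<sub>s</sub> draw, keeping memory bounded while α is
  still counted over every tested pair.
- JSON serialization covers restraint parameters, filter results, and the
  full run report (config echo, per-leg values, errors, α, overlap,
  effective sample sizes, software version).

## Known limitations

- Flexible ligands: the conformer-alignment Jacobian is neglected
  (standard practice, exact only for rigid/single-atom ligands); strongly
  flexible guests would need an internal-coordinate treatment.
- The MBAR standard error assumes effectively independent samples; the
  decorrelation stage provides that for trajectories, but restraint-fit
  noise is not propagated (it cancels in expectation and was measured to
  be within the reported se across seeds at the validation sizes).
- Only the two-state MBAR problem is implemented (the cycle needs no
  more); the solver generalizes to K states but is not exercised there.
- Real-energy backends (e.g. OpenMM with OBC2) are plug-ins behind the
  `EnergyBackend` protocol; this package ships only toy backends and does
  not run MD.
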