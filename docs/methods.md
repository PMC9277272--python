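# Methods

## The scaling model

The package treats a chain of `N` Kuhn segments of length `a` (Å) whose
size obeys `Rg = k(α) a N^α`.  Two prefactors are geometrically exact:
the fully stretched rod has `Rg0 = aN/√12` (α = 1), and the ideal chain
has `Rg = a√(N/6)` (α = 1/2).  Between and beyond these anchors the
prefactor is interpolated as `k(α) = 1/√(12α)`.  This interpolation is a
modelling assumption, not a derivation — it is the simplest smooth form
that passes through both anchors — and everything downstream (the
exponent inversion, the dimensionality profile) inherits it.

The inversion solves

    f(α) = −½ ln α + (α − 1) ln N − ln(Rg/Rg0) = 0.

`f` is strictly increasing only for α > 1/(2 ln N); below that the left
side turns over and the root is not unique.  Root-finding (Brent, to
machine tolerance; reported equation residuals are < 1e−9) is therefore
restricted to the increasing branch `[max(1/(2 ln N) + 0.01, 0.20), 1.25]`.
A measured Rg outside the attainable range of that branch — compacted
below the branch minimum, or transiently stretched beyond Rg0, which real
trajectory frames do — is clamped to the bracket edge and flagged
(`clamped_low` / `clamped_high`) rather than raised, so a profile is
always produced.  The upper edge 1.25 deliberately admits over-stretched
estimates; the dimensionality `D = 1/α` is meaningful only for α ≤ 1, so
rows with α > 1 report D = 1 with the `clamped_high` flag.

Chain-parameter convention: `N` is the segment (residue) count and
`a = L/N` with `L` the stretched contour length.  A *discrete* rod of N
segments (N+1 beads) has `Rg = a√(N(N+2)/12)`, slightly above the
continuous `L/√12`; model predictions use the continuous forms, while
geometry on coordinates evaluates the unweighted RMS-from-centroid sum
exactly.  This is why a stretched discrete chain analyzed against
`Rg0 = L/√12` lands marginally above α = 1 — expected behaviour, handled
by the clamping policy.

### Reporting policy

Two report modes exist because hand calculations done at printed
precision propagate rounding: `full_precision` (default) carries the
unrounded root (Rg = 6.97 Å, N = 20, L = 73.61 Å gives α ≈ 0.5182,
D ≈ 1.93), while `rounded` rounds α to two decimals before
computing D (α = 0.52 → D = 1.92).  Columns are written at four decimals
either way.

### Sphere prefactor

For the compact globule the embedded-sphere radius comes from the total
chain volume, `R = (3Nv/4π)^(1/3)` with per-segment excluded volume `v`
(default `a³`), and the sphere's radius of gyration uses the
about-centre value `√(3/5) R`.  The about-an-axis value `√(2/5) R` is
sometimes quoted in this context; `√(3/5)` is the one consistent with
the unweighted segment definition of Rg used everywhere else in the
package, and with the worked Trp-cage numbers (R = 6.19 Å → Rg = 4.8 Å).
The globule benchmark exponent is taken as exactly 1/3 (not a decimal
truncation like 0.33, which shifts the predicted Rg by ~0.03 Å).

## Flory theory

The free energy is implemented in proportional (dimensionless) form,
`F(L) = N²v/L³ + L²/(Na²)`: only the minimizer location is meaningful,
so the temperature prefactor is dropped.  `flory_minimize` locates the
stationary point of the implemented F by bracketed root-finding on its
derivative (upper bracket doubled until the sign changes), and carries
the closed form `L* = ((3/2)N³va²)^(1/5)` alongside as a consistency
check; agreement is at machine precision, comfortably inside the 1e−6
relative contract.  Fitting `ln L*` against `ln N` over any geometric
ladder returns slope 3/5 exactly (the relation is a pure power law); the
renormalization-group refinement α = 0.588 is used only as the reference
value for the SAW ensembles, never computed.

## Exponent estimators

All exponent fits are ordinary least squares (`scipy.stats.linregress`)
on log-transformed variables: `ln Rg` on `ln N` for ensemble scaling,
`ln L*` on `ln N` for Flory, `ln T` on `√N` for the folding-time law.
OLS (not orthogonal regression) is the deliberate choice: in every use
here the abscissa (N) is exact and only the ordinate carries noise.
Duplicate N values are rejected rather than averaged.

## Synthetic ensembles

No external structures are required: the generators realize each chain
class the theory describes, with defaults chosen as the study
conditions.

- **Stretched rod** — N+1 collinear beads spaced a; end-to-end exactly
  Na.
- **Freely jointed chain** — N bonds of exact length a with iid uniform
  directions; `⟨Ree²⟩ = Na²` and `⟨Rg²⟩ = Na²/6` to sampling error
  (verified within 5 % / 8 % at N = 100, 10⁴ samples).
- **Self-avoiding walk** — pivot algorithm on the simple cubic lattice:
  from a straight rod, apply a random non-identity octahedral symmetry
  (47 signed permutation matrices) to the suffix past a random site and
  reject self-intersections; self-avoidance of proposals reduces to a
  prefix/suffix overlap test because lattice symmetries preserve the
  suffix's internal distinctness.  Defaults: burn-in 10·N attempted
  pivots, stride N between retained states — standard equilibration for
  pivot chains, overridable.  The pivot algorithm is used because naive
  chain growth attrites beyond N ≈ 50.  At the reference sampling scale
  (N ∈ {20, 40, 80, 160}, 2000 samples each) the fitted exponent lands
  within 0.02 of 0.588; these N are far from the asymptotic regime, so
  the agreement is a finite-size result, not a renormalization-group
  computation.
- **Compact globule** — sequential placement with exact bond length a,
  hard-core non-bonded separation 0.8a, confined to a sphere of radius
  1.1 × the embedded-globule radius; dead ends backtrack, and after a
  bounded number of failures a deterministic space-filling spherical
  spiral (bond length preserved by chord bisection) takes over.  At the
  default density the packing fraction is ≈ 0.2 and stochastic placement
  essentially always succeeds.  Mean Rg across N fits an exponent inside
  [0.30, 0.38].
- **Folding trajectory** — frame j applies seeded crankshaft rotations
  (interior beads rotated about the axis joining two random beads) to
  the previous frame, then rescales radially about the centroid so the
  frame's Rg equals the model prediction `rg_from_alpha(α_j, N, a)`
  (exact up to floating point; contract 1 %).  A crankshaft is the
  identity on a collinear section (the interior lies on the rotation
  axis), so degenerate moves fall back to a small pivot rotation of the
  chain suffix, letting the initially straight chain develop
  three-dimensional structure.  The radial rescaling does not preserve
  bond lengths — accepted, because only Rg enters the estimator.  This
  synthesizer is a stand-in for real intermediate-state ensembles, whose
  construction the scaling theory does not prescribe.

Reproducibility contract: every random stream is
`SeedSequence((seed, stream_id, sample_index))`, so identical configs
are bit-identical and growing `n_samples` never reshuffles earlier
samples; the SAW Markov chain is a single stream per call, which
satisfies the same contract (extending the chain appends samples).

## What the synthetic data does and does not show

The generators emulate homopolymer geometry only: no force field, no
hydrophobic-sequence heterogeneity, no solvent, no kinetics.  Passing
the schedule-recovery test shows the estimator inverts its own forward
model correctly per frame — it does not validate the k(α) interpolation
against real protein ensembles, whose residual structure (helices,
salt bridges, the Trp cage itself) the beads do not carry.  Likewise the
B-factor thresholds (< 30 Å² confident, > 60 Å² disordered, boundaries
intermediate) are conventional cutoffs applied as pure numbers.

## Geometry and superposition

Rg, end-to-end and RMSD operate on equal-mass bead coordinates;
mass-weighting is out of scope.  Superposition uses the least-squares
proper rotation (SVD/quaternion route via scipy `align_vectors`,
reflections corrected), with the residual RMSD computed from the
transformed coordinates rather than the singular-value identity — the
latter loses ~7 digits to cancellation on near-congruent pairs and
would mask the 1e−9 invariance the pipeline promises.  RMSD defaults to
superposed (structure-comparison usage); the raw option exists for
drift diagnostics.  RMSF aligns every member onto a reference (default:
the first member) and reports per-bead RMS deviation about the aligned
mean.

## File formats and pipeline

Multi-MODEL PDB is read and written through Biopython: one conformation
per MODEL (a file without MODEL records is one conformation), selection
`ca` keeps atoms named CA with blank or 'A' altloc, residue numbering is
preserved as printed, and unequal atom counts across MODELs are a format
error.  XYZ is the interchange format for synthetic beads (they have no
atom identities): count line, comment line — optionally carrying a
`t= <ps>` token parsed as the frame time — and `element x y z` rows at
six decimals, lossless round trip at that precision.  Profiles are TSV
with a fixed header (`frame time_ps rg_A ree_A rmsd_A alpha dimension
flag`), floats at four decimals, missing RMSD as `NA`; identical inputs
and seed give byte-identical output.

When the contour length is not supplied, the analysis infers `L = N·a`
if a segment length is given, else the maximum observed end-to-end
distance — logged prominently, since every α in the profile depends on
`Rg0 = L/√12`.  The dimensionality-versus-Rg curve for a trajectory is
obtained by plotting the `dimension` column against `rg_A` from the
profile TSV (for the worked Trp-cage parameters: N = 20, L = 73.61 Å);
no plotting code ships in the core.

## Problem sizes

Reference computations are sized for a desk machine: the Flory ladder
runs N up to 3200 (sub-second), and the SAW reference scale is 2000
retained pivot states at each of N ∈ {20, 40, 80, 160} (~20 s on one
CPU).  Unit tests use smaller ensembles with correspondingly widened
statistical bands; the full-scale checks live in the acceptance suite.

## Known limitations

- The k(α) interpolation is asserted, not derived; α estimates inherit
  whatever bias it carries for partially folded real chains.
- Estimates below the branch minimum or above 1.25 are clamped, not
  extrapolated; heavily collapsed frames (α near 1/3 at small N) sit
  close to the non-monotone turnover where sensitivity to Rg is high.
- Lattice SAWs at N ≤ 160 are pre-asymptotic; the fitted exponent is
  resolution-limited to about ±0.01 even with perfect sampling.
- No mass weighting, no periodic boundaries, no all-atom selections
  beyond CA/all.
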