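# bioscaling

Topological scaling analysis of polymer and protein chains: estimate the
polymer scaling exponent α — and with it the fractal dimensionality
D = 1/α — of a chain at any stage of folding, from nothing more than its
radius of gyration.

## The idea

Scaling relationships tie the size of a chain of *N* Kuhn segments of
length *a* (Å) to a power law, L ~ a N<sup>α</sup>.  The exponent marks
the folding stage: α = 1 for the fully stretched chain (a one-dimensional
object), α = 1/2 for the ideal chain at the theta point, α ≈ 0.588–0.6
for an excluded-volume coil in good solvent, and α = 1/3 for a compact
globule.  The fractal dimensionality D = 1/α therefore runs from 1
(line) through 2 (ideal coil) to 3 (globule) as the chain folds.

The package pins the radius of gyration to the exponent with the
interpolated law

  R<sub>g</sub>(α) = k(α) · a N<sup>α</sup>,  k(α) = 1/√(12 α),

whose anchors k(1) = 1/√12 (rod) and k(1/2) = 1/√6 (ideal chain) are
geometrically exact.  Given a measured R<sub>g</sub> and the chain
parameters (N, a), solving

  ln(R<sub>g</sub>/R<sub>g0</sub>) = −½ ln α + (α − 1) ln N,  R<sub>g0</sub> = aN/√12

for α on its monotone branch yields the exponent per trajectory frame —
a super-fast read-out of the folding stage that works for proteins and
synthetic polymers alike.  Supporting pieces: the Flory excluded-volume
free energy F(L) ∼ N²v/L³ + L²/(Na²) and its minimizer (which fixes
α = 3/5), coordinate-level geometry (R<sub>g</sub>, end-to-end distance,
Kabsch RMSD, RMSF, B-factor confidence classes), OLS exponent fits on
(N, R<sub>g</sub>) ensembles, and seeded generators for every chain
class — stretched rods, freely jointed chains, pivot-sampled
self-avoiding walks on the cubic lattice, compact globules, and
synthetic folding trajectories that follow a prescribed α(t) schedule.

Who it is for: structural bioinformaticians and polymer physicists who
want a dimensionality read-out of folding trajectories (multi-MODEL PDB
or XYZ) without running heavyweight simulation analysis stacks.

## Worked example

The package's running example is the 20-residue Trp-cage miniprotein:
N = 20 segments, extended contour length L = 73.61 Å, so a = L/N =
3.68 Å.  Synthesize a folding trajectory whose exponent ramps linearly
from the stretched chain (α = 1) to the globule (α = 1/3) and analyze
it:

```sh
bioscaling generate --model folding --n 20 --a 3.6805 --frames 50 --seed 1 --out fold.xyz
bioscaling analyze --traj fold.xyz --n 20 --length 73.61 --rounded --out fold_profile.tsv
```

`fold_profile.tsv` holds one row per frame:

```
frame	time_ps	rg_A	ree_A	rmsd_A	alpha	dimension	flag
0	0.0000	21.2494	70.1801	NA	1.0000	1.0000	ok
1	1.0000	20.5409	67.8402	NA	0.9900	1.0101	ok
...
49	49.0000	4.9952	16.4981	NA	0.3300	3.0303	ok
```

The first frame sits at the stretched-chain radius of gyration
R<sub>g0</sub> = L/√12 = 21.25 Å with D = 1; by the last frame the chain
has compacted to R<sub>g</sub> = 5.0 Å, α = 1/3, D ≈ 3 — a globule.
Plotting `dimension` against `rg_A` from this TSV reproduces the
dimensionality-versus-compactness curve of the folding transition.

The same inversion from Python, for the folded-state radius of gyration
R<sub>g</sub> ≈ 6.97 Å observed in Trp-cage folding simulations:

```python
>>> import bioscaling as b
>>> b.alpha_from_rg(6.97, contour_length=73.61, n_segments=20)
ScalingEstimate(alpha=0.5182, dimensionality=1.9299, rg=6.97, residual=0.0, flag='ok')
```

so the folded state sits just above the theta point: α ≈ 0.52, D ≈ 1.92
at two-decimal rounding — the molecule has passed from D = 1 to nearly
D = 2 and is not yet a perfect globule (which would require
R<sub>g</sub> ≈ 4.8–5.0 Å for this chain).

Flory theory, numerically:

```python
>>> print(b.flory_exponent([50, 100, 200, 400, 800, 1600, 3200], 3.6805**3, 3.6805).summary())
OLS fit of ln L* on ln N (7 points)
  slope      0.600000 +/- 0.000000
  intercept  1.384142
```

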