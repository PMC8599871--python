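# Methods

## The two-phase model

A torsionally constrained DNA tether under tension F and imposed turns n_t
is modelled as a series combination of two helical phases. Each phase is an
inextensible worm-like chain obeying the Marko–Siggia interpolation

    F = (kT / L_p) [ -1/4 + 1/(4 (1 - x)^2) + x ],  x = L_e / (N_b L_0),

with its own persistence length L_p and rise per base pair L_0. Negative
supercoiling above ~1 pN converts a fraction χ of base pairs from the B to
the L form; χ is taken linear in turns between the buckling bound n_b,max
(χ = 0) and the completion threshold n_t,max (χ = 1), with n_t,max derived
from the supercoiling threshold σ_max = -1.8 via σ = n_t/(N_b/10.4) rather
than hard-coded, so tethers of different length are handled by one rule.
The mixed extension is the χ-weighted sum of the two pure-phase WLC
extensions; it is exactly linear in n_t at fixed force, and its slope
changes sign at the inversion force F*, the unique tension at which the
pure-phase extension curves cross. Uniqueness holds whenever the L form is
both longer per bp (L_0L > L_0B) and floppier (L_pL < L_pB); both
preconditions are enforced.

Key assumptions: phase coexistence is ideal (no domain-wall energy, no
torque bookkeeping); the B and L phases are mechanically homogeneous;
sequence effects enter only through the phase parameters. The model is not
valid where plectonemes form (low force, or |σ| beyond the threshold); the
trace generator handles those regimes with an explicitly qualitative
surrogate (below).

## Parameters, units, defaults

Units are fixed package-wide: nm, pN, pN·nm, turns; σ dimensionless.

| parameter | default | meaning |
|---|---|---|
| L_pB | 50 nm | B-form persistence length |
| L_0B | 0.34 nm | B-form rise per bp |
| L_pL | 3–3.8 nm | L-form persistence length (the inferred quantity) |
| L_0L | 0.48 nm | L-form rise per bp (ratio 1.4 used for inference) |
| kT | 4.28 pN·nm | thermal energy at 310 K |
| N_b | 4642 bp | tether size (alternative construct: 6258 bp) |
| σ_max | -1.8 | supercoiling at complete B→L conversion |
| n_b,max | 0 turns | buckling bound; magnitude ≤ 30, negligible in the BL window |
| r | 0.92 nm | backbone helix radius (geometry reconstruction) |

The temperature behind kT is a modelling choice (no single convention
exists for MT experiments near physiological conditions); 310 K is used and
kT is configurable everywhere. n_b,max defaults to 0 because it is small
against the ~800-turn BL window; it is a visible config knob (±20–30) for
sensitivity checks.

## Inverse inference

At F* the two fractional extensions satisfy x_L = x_B / (L_0L/L_0B). The
L-form persistence length therefore has the closed form
L_pL = (kT/F*) g(x_L) with g the Marko–Siggia response and x_B obtained by
inverting the B-phase force law at F*. This closed form round-trips through
the forward root-solve to better than 1e-6 pN (tested). The rise ratio
itself comes from geometry: all duplex phases share one backbone, so the
arc length per bp s = sqrt(L_0B² + (2πr/10.4)²) is conserved; at the
completion threshold the residual twist per bp is |1+σ_max|/10.4 turns, and
solving the same relation for the L rise gives L_0L/L_0B ≈ 1.40 at
r = 0.92 nm. The supplementary derivation behind the published ratio is not
public; this reconstruction is the package's own, the radius sits inside
the accepted 0.9–1.0 nm range for the B-DNA backbone helix, and it is an
explicit config knob, never silent. Note the ratio grows (slowly) with
radius in this construction.

The compatibility-region map evaluates the forward F* on a (ratio, L_pL)
grid and masks points within ±ΔF of a measured value; grid points where the
inversion force is undefined (e.g. L_pL ≥ L_pB) are flagged and masked
rather than raised, so the map always renders.

## Numerics

WLC inversion uses Brent bracketed root finding on x ∈ [0, 1 - 1e-9]
(xtol 1e-12): the force law is strictly monotone there, so convergence is
guaranteed; agreement with a plain bisection oracle is tested to 1e-8.
The inversion-force search brackets F ∈ [0.01, 50] pN (xtol 1e-10),
spanning all experimentally relevant tensions. WLC fitting minimises
extension-space residuals (extension is the measured quantity in MT) with
scipy least_squares, bounds (0, ∞), initial guess (max extension / 0.95,
50 nm); standard errors come from the Jacobian with the usual residual-
variance scaling. Negative or zero forces are rejected, not extrapolated:
the model is only used at positive tension. Supercoiling/turns conversions
are plain arithmetic; round trips are exact to ≤ 1 ulp (IEEE double does
not permit bit-exactness for every integer input).

## Trace segmentation

The published analysis reports per-regime slopes but not how regime
boundaries were chosen; the procedure here is therefore declared, not
inferred. Each trace is segmented by exhaustive search over ordered
breakpoint pairs on the observed turn values, scoring three independent
least-squares lines per candidate via prefix-sum algebra (O(1) per
candidate, so ~10³-point traces are desk-scale). Ties are broken by the
longest middle segment, then the smaller first breakpoint; a trace whose
single-line fit matches the three-segment optimum is flagged
"single-regime suspected". Slope fits exclude the innermost 10% of each
segment's points adjacent to a breakpoint (configurable) to reduce
junction-curvature bias. F* is the linear interpolation of the per-force
mean BL slope across its sign change; its confidence interval resamples
whole traces within each force level (1999 bootstrap replicates, seeded) to
respect within-trace correlation. Fixed turn windows (e.g. the BL fit over
-700 ≤ n_t ≤ -100) are supported so figure-style analyses are reproducible;
every estimate carries the window it used.

## Synthetic data

The generator emulates MT twist scans: piecewise-linear extension in turns
(plectonemic B branch, mixed BL branch from the model itself, plectonemic L
branch), continuous at the junctions by construction, plus i.i.d. Gaussian
axial noise of 10 nm — the tracking precision of bead imaging along the
optical axis — and clipping at zero extension with a per-point flag.
Because the generator calls the very model operations the pipeline fits,
zero-noise traces equal the model exactly; this generator/model identity is
asserted by cross-module tests. Below 0.5 pN the B→L transition loses to
writhing, so low-force traces are symmetric plectonemic shortening on both
sides of the buckling point.

What the generator does *not* emulate: drift, bead-size variation,
correlated (Allan-type) noise, torque signals, partial Z-DNA content, or
quantitative plectonemic slopes. The plectonemic branches use a loop-
balance surrogate, c·2π·sqrt(kT·L_p/(2F)) with c = 0.4 calibrated to put
low-force B slopes in the tens of nm/turn; it reproduces only the
monotonicities (slope falls with force, grows with L_p) and is prominently
not a quantitative model — measured L-regime slopes in the literature fall
well below loop-balance estimates, which no surrogate of this family can
arbitrate. Consequently, passing recovery tests demonstrate correctness of
the inference machinery under the stated noise model, not robustness to
every artifact of real bead tracking.

## Study conditions and problem sizes

Simulated campaigns use 9 forces evenly spaced over 1–4 pN, 3 traces per
force, turn scans from +100 down to -900 in steps of 5 (a realistic twist-
scan density), noise sd 10 nm, on the 4642 bp tether. The end-to-end
recovery study repeats this over 50 seeded campaigns and checks the median
L_pL recovery error; the WLC-fit recovery study uses 50 force points over
0.1–8 pN and 100 seeds. All stochastic outputs are fully determined by
(seed, config).

## Known limitations

- No torque or free-energy treatment of coexistence; χ is imposed, not
  derived from a chemical potential.
- The geometric rise-ratio reconstruction depends on the assumed backbone
  radius (±0.05 nm in r moves the ratio by ~±0.02).
- The plectonemic surrogate is qualitative only; B/L-regime slope values
  from it should never be compared quantitatively with experiments.
- Whether the published inference used L_pB = 50 nm or the fitted
  44.3/48.2 nm values is not stated; 50 nm is the default frame here, and
  the choice moves the inferred L_pL by a few percent.
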