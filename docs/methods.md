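# Methods

## Model

A single prototypical islet is treated as a well-mixed compartment. Newly
secreted insulin enters as hexamers at rate `s(G)/6` (the secretion rate
`s(G)` counts monomer equivalents; one hexamer carries six), dissolves into
dimers (rate `p`, with mass-action re-aggregation `q·d³`) and then monomers
(rate `p_hat`, re-aggregation `q_hat·m²`). Local monomer is lost to the
peripheral circulation at rate `c` and degraded at rate `d_i`; the returned
peripheral monomer pool is fed proportionally to local monomer production
(coefficient `k`) and degraded at the same `d_i`. Blood flow itself is not
modelled: islet capillaries are fenestrated enough that transport barriers
are negligible, and flow in and out of the islet balances, so its rate
cancels. Glucose enters only through the secretion response and is clamped
(piecewise-constant protocols only); coupled glucose–insulin dynamics,
receptor binding and spatial structure are out of scope.

The stoichiometric factors (÷6 on secretion, ×3 hexamer→dimer, ×2
dimer→monomer) are the unique mass-consistent choice given that one hexamer
yields three dimers and six monomers.

The system is cooperative (off-diagonal Jacobian entries nonnegative on the
nonnegative orthant) and has a unique equilibrium in closed form; standard
monotone-systems theory then gives global asymptotic stability. Rather than
reproducing that proof apparatus, the test suite verifies the conclusions
numerically: forward-invariance of the nonnegative orthant (the vector field
points inward on every coordinate face), boundedness, and convergence of 100
random initial states (components up to 10⁴ pM, glucose 0–25 mM) to within
0.1% of the closed-form equilibrium by t = 1000 min.

## Parameters

| symbol | meaning | default | units | origin |
|---|---|---|---|---|
| `sigma` | maximum secretion rate | 112.0 | pM/min | least-squares fit |
| `alpha` | half-saturation glucose | 9.40 | mM | least-squares fit |
| `gamma` | Hill exponent | 3.15 | – | least-squares fit |
| `p` | hexamer→dimer dissolution | 0.5 | min⁻¹ | shared by fast/slow formulations in the subcutaneous-absorption literature |
| `q` | dimer→hexamer aggregation | 1.58×10⁻¹⁵ | L²/pmol² | Semilente coefficient 7.6×10⁻² ml²/U², converted |
| `p_hat` | dimer→monomer dissolution | 1.0 | min⁻¹ | must exceed `p`; equilibria insensitive |
| `q_hat` | monomer→dimer aggregation | 10⁻⁷ | L/pmol | order of magnitude; negligible at pM |
| `d_i` | insulin degradation | ln2/6 ≈ 0.1155 | min⁻¹ | 6-min in-vivo half-life (literature range 4–6 min) |
| `c` | local→peripheral transfer | 0.3845 | min⁻¹ | total monomer clearance 0.5 min⁻¹ minus `d_i` |
| `k` | peripheral return coefficient | 3·d_i ≈ 0.3466 | min⁻¹ | 75% equilibrium peripheral share via `I_p*/m* = k/d_i` |

Unit bridge: 1 U/ml of insulin activity = 6.94×10⁶ pM. This is the unique
convention under which the published aggregation-coefficient table rows
(Lispro, Actrapid, Semilente, NPH/Glargine) are simultaneously consistent
between their ml²/U² and L²/pmol² columns to the printed two significant
figures; comparisons therefore use 5% relative tolerance.

### Calibration choices

`d_i` follows from exponential decay halving in one half-life. The pair
`(c, k)` cannot be read off the literature; they are pinned to two published
model *outputs*: the 75%/25% peripheral/new monomer split (fixing
`k = 3·d_i`) and the validated dose-response magnitudes (fixing
`c + d_i = 0.5 min⁻¹`, since `I_p* = (k/d_i)·s(G)/(c + d_i)`). Both anchors
are plain config values (`CalibrationAnchors`), overridable from TOML, not
buried constants. The surviving-fraction argument — 50% hepatic first-pass
extraction times transit decay `exp(−d_i·25 s)` ≈ 0.476 of each islet's
output returning per circulation — is implemented (`return_fraction`) and
tested, but is *not* used to derive `k`: no mapping from that dimensionless
fraction to a rate constant reproduces both printed anchors, so the relation
is left explicit but unreconciled.

`c` (monomer loss to circulation) and `k` (return coefficient) are kept as
distinct parameters: hepatic extraction and transit degradation intervene
between leaving and returning, so the two fluxes need not share a
coefficient. Setting `k = c` remains representable.

### Secretion fit

Unweighted least squares of the Hill triple on the packaged seven-point
secretion table (glucose 3–25 mM, rates 1–103 pM/min; three of the rows are
anchor points estimated on the curve, used exactly as published). The SSE
surface is multimodal in `gamma`, so the fit is multi-start (3×3×4 grid over
sigma/alpha/gamma) bounded local optimisation (`scipy.optimize.least_squares`,
TRF, boxes sigma ∈ (0,500], alpha ∈ (0,50], gamma ∈ [1,6]); best SSE wins,
ties broken toward the smallest exponent. The result (σ=112.0, α=9.40,
γ=3.15, SSE=102.9) is cross-checked in the tests against an independent
dense grid-search oracle. The fitted maximum rate is treated as pM/min
(saturating output), matching the units of the data column it is fitted to.

## Synthetic data

The generator emulates the *structure* of the secretion table: the seven
glucose design points, rates on a known Hill curve plus additive Gaussian
noise (sd in pM/min) truncated at zero. Absolute (not relative) noise is
adequate at these magnitudes for recovery testing. All generators are pure
functions of (spec, seed) via `numpy.random.default_rng`. What passing the
recovery tests shows: the fitting pipeline is unbiased (<5% in σ at sd
5 pM/min) *under this error model and design*; real secretion data have
correlated, possibly heteroscedastic errors and uncontrolled glucose, which
the generator does not emulate.

## Numerics

- Integrator: `solve_ivp` LSODA, rtol 10⁻⁸, atol 10⁻¹⁰ pM; default initial
  condition the empty islet (global stability makes equilibria
  initial-condition-free).
- The simulated trace is validated against the matrix-exponential solution
  of the linear cascade (aggregation off) to 10⁻⁶ relative error, and the
  step-response timing against a root-find on that closed form (90% rise
  time 25.54 min after a 0→10 mM step; 50% at 11.37 min).
- `time_to_fraction` interpolates linearly between output samples and
  returns `None` ("not reached") when the band is never entered — the
  trajectory approaches equilibrium monotonically and has no finite-time
  maximum, so "reaching its maximum" is operationalised as coming within
  10% of equilibrium.
- Degenerate inputs: zero glucose (or `sigma→0`) gives the zero equilibrium
  and the dose-sweep emits null source fractions there; fits require ≥3
  distinct glucose values; parameter invariants (`p_hat > p`, positive
  rates, clearance > `d_i`) are enforced at construction.
- Monte-Carlo recovery tests use a reduced 3-point start grid for repeated
  fits (the SSE surface is unimodal near the truth at these noise levels);
  the full grid is used everywhere a single fit is reported. Problem sizes:
  200 replicates at sd 3 for the median-error check, 500 at sd 5 for the
  bias check, 100 random states for the stability suites.

## Known limitations

- The model is deliberately blind to intra-islet spatial structure, blood
  flow direction, receptor binding/internalisation and non-glucose
  secretagogues.
- The low-glucose validation point is overpredicted (≈81 pM vs 57 pM
  observed at 5 mM; ~42% relative) — the Hill fit is constrained mostly by
  the mid/high-glucose points; the hyperglycemic clamp point agrees to
  <1%.
- The published claim that newly released monomer plateaus near 100 pM at a
  15 mM clamp is inconsistent with the validated dose-response plus the
  75/25 split, which together force m* ≈ 180 pM there; the package follows
  the validated table and documents the discrepancy (it is asserted, not
  hidden, in the test suite).
- Equilibrium predictions are provably insensitive to `p`, `p_hat`, `q`,
  `q_hat` (the chain passes the full secretion flux at steady state), so
  transient shapes — which do depend on them — inherit the uncertainty of
  those literature-derived rates and should be read qualitatively.
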