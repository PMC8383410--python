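# Methods

## Model

The community is a four-compartment ODE system: a perennially active
(PA) prey `p`, a dormitive prey split into an active form `y1` and a
dormant form `y2`, and one predator `z`. Densities are mg L⁻¹, rates
day⁻¹. The structural assumptions are:

1. the dormant form is sterile — only `y1` reproduces;
2. the dormant form exerts no crowding — the shared logistic factor is
   `1 − (p + y1)/K`;
3. predator mortality is density-independent (constant `d_z`);
4. all three prey compartments are consumed through Holling type-II
   responses `f_q(q) = c_q q/(1 + c_q h_q q)`, linear at low density and
   saturating at `1/h_q`;
5. the allocation of dormitive reproduction to active offspring is a
   decreasing sigmoid of predator density,
   `μ(z) = χ + φ/(1 + exp((z − η)/σ))`, the remainder `1 − μ(z)` going
   to dormant offspring; dormant individuals re-activate at rate `α`.

With `y1 = y2 = 0` the system reduces *exactly* to the two-species
Rosenzweig–MacArthur model; the package carries an independently coded
two-species right-hand side (`rm_reference`) and the test suite asserts
the reduction both at the level of the vector field (1000 random states)
and of whole trajectories (agreement to 1e-8 at every sample).

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| `r_p`, `r_y` | prey maximum growth rates | 0.55, 0.5 | day⁻¹ |
| `K` | prey carrying capacity | 11 | mg L⁻¹ |
| `d_z` | predator death rate | 0.2 | day⁻¹ |
| `alpha` | dormancy termination rate | 0.05 | day⁻¹ |
| `k_p`, `k_y1`, `k_y2` | predator growth efficiencies | 0.5, 0.5, 0.25 | — |
| `c_p`, `c_y1`, `c_y2` | foraging efficiencies | 1, 1, 0.4 | day⁻¹ mg⁻¹ L |
| `h_p`, `h_y1`, `h_y2` | handling times | 0.5 | day |
| `eta`, `sigma` | switching threshold, width | 1, 0.1 | mg L⁻¹ |
| `chi`, `phi` | switching lower bound, range | 0.2, 0.75 | — |

The reference initial community is (p, y1, y2, z) = (2, 2, 0, 1) mg L⁻¹.
Two unit conventions deserve a note: the growth rates `r_p`, `r_y` are
per-day rates (their role in the logistic term admits nothing else, and
this keeps them commensurate with `d_z`), and `χ`, `φ` are dimensionless
— `μ` is a fraction in [0, 1], which is also why validation enforces
`0 ≤ χ ≤ χ + φ ≤ 1` (with 1e-9 slack so grid values summing to 1 up to
float rounding are not rejected). The defaults put the two-species
subsystem deep in its limit-cycle regime (the coexistence equilibrium at
p\* = 0.5, where `k_p f_p(p) = d_z`, is unstable for K ≳ 3).

## Numerics

Integration uses the Bogacki–Shampine explicit Runge–Kutta (2,3) pair
with `rtol = atol = 1e-8`, implemented as a numba-compiled driver
(standard embedded-pair error control: RMS norm against
`atol + rtol·max(|y|, |y_new|)`, safety 0.9, step factor in [0.2, 10],
FSAL). Parameter sweeps run thousands of 3000-day integrations; the
compiled loop does one in ~40 ms where a Python-level stepper needs
seconds, which is what makes desk-scale winner maps interactive. The
driver is validated against scipy's implementation of the same pair
(max state discrepancy < 1e-3 mg L⁻¹ over 500 days, the two tracking
each other far more closely than either tracks the true solution) and
against an order-8 pair at 1e-10 over the first 150 days. Beyond
~150 days *any* low-order pair at 1e-8 accumulates tolerance-level phase
drift along the large-amplitude cycles (scipy's RK23 drifts identically),
so trajectory-level comparisons across solvers are only meaningful early;
the reported metrics (reversal times, extinction times, winners) are
solver-independent to well under their own tolerances and the test suite
asserts that directly.

Dense output is sampled every `output_dt = 0.1` day through the cubic
Hermite interpolant of each accepted step; the sampling grid is
presentation only (halving it changes no metric) and resolves the 25–50
day population cycles to well under 1 % of a period. Inside the
right-hand side, tiny negative densities from solver undershoot are
clamped to zero in the response and crowding terms only — stored
trajectories keep the raw values, and any stored value below −1e-6 is
treated as solver failure. The sigmoid exponent is clamped at ±700 so
extreme predator densities return `χ` (resp. `χ + φ`) exactly instead of
overflowing. No compartment is ever zeroed during integration:
extinction is a post-hoc diagnosis, never an event acting on the state.
There is no randomness anywhere; repeated runs are bit-identical.

## Competition diagnostics

* **Peaks.** Interior strict local maxima of the sampled series
  (plateaus count once, at their midpoint; endpoints never count),
  ignoring values below a 1e-6 mg L⁻¹ floor (solver-scale ripple on
  near-extinct series). Each peak is refined by a parabola through the
  three surrounding samples, so peak *times* resolve below `output_dt` —
  needed to report a reversal time as 195.0 rather than "somewhere in
  [195.0, 195.1)".
* **Extinction time.** First sample time after which the density stays
  below the threshold (default 1e-3 mg L⁻¹, three orders below the
  initial densities) through the end of the run; transient dips with
  recovery do not count. Reported times are also quoted rounded to the
  nearest 10 days, which is the honest precision of the diagnosis: the
  exact value depends on an arbitrary threshold crossing a steep
  exponential decay.
* **Reversal time `T_w`.** The time of the first `y1` peak whose density
  strictly exceeds the density of the *most recent preceding* `p` peak.
  Earlier `y1` peaks arriving before any `p` peak are skipped; after the
  PA prey's extinction its last recorded peak remains the comparison
  standard. Of the defensible pairing rules (preceding peak,
  same-cycle peak, global-so-far maximum) the preceding-peak rule is
  implemented because it reproduces the reference reversal times at
  K = 13 and K = 20 to 0.1 day; the choice is localised in
  `metrics.reversal_time`.
* **Winner.** Over a late "stable competition" window (default
  t ∈ [2800, 3000]) the competitor with the strictly higher maximum
  density wins, provided that maximum clears the extinction threshold;
  both below threshold, or an exact tie, is "none".

## Parameter sweeps

`run_grid` crosses two axis grids, overriding the base parameters cell
by cell; cells violating a joint constraint (`χ + φ > 1`, or a panel's
extra condition such as `c_y2 ≤ min(c_p, c_y1)`) are masked infeasible
rather than dropped, so grids keep their shape. Each feasible cell is an
independent integration from (2, 2, 0, 1) to the window end — cells can
run in parallel (joblib) with results identical to serial. The six
canonical panels pair (K, α), (K, d_z), (χ, φ), (η, σ), and the growth
and foraging efficiencies; in the last two the PA-prey and active-form
parameters ride one tied axis (`k_p = k_y1`, `c_p = c_y1`), with
`untie=True` as the escape hatch. Axis ranges default to brackets around
the reference values wide enough to contain the regime boundaries
(K ∈ [5, 25], α ∈ [0, 1], d_z ∈ [0.05, 0.5], χ, φ ∈ [0, 1], η ∈ [0.2, 3],
σ ∈ [0.01, 1], k ∈ [0.1, 0.9], c ∈ [0.2, 2]); the default resolution is
21 × 21, and the test suite exercises the panel properties at 11 × 11 —
about 350 integrations, under ten seconds with the compiled driver.

## What the simulations do and do not show

This is a deliberately minimal deterministic model. The winner maps and
reversal times characterise *this* ODE system; they abstract away
demographic stochasticity (a density of 1e-176 mg L⁻¹ still "exists"
here), spatial structure, seasonality, evolution of the switching
function, and more than one dormitive morph. Near regime boundaries the
winner can rest on long transients, so window placement matters and is
therefore explicit everywhere. Extinction times in particular inherit an
arbitrary threshold: the PA prey's final decline at the reference
parameters crosses 1e-3 mg L⁻¹ transiently at t ≈ 373, pops back up to
0.067 mg L⁻¹ at t ≈ 416, and only then falls for good (t = 420.6) — a
visual reading of the trajectory would call it extinct around day 380,
the threshold rule says 420, and both descriptions are in the docstrings
so users know which number they are getting.
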