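# Methods

## The removal model and its domain

Areal N removal is modelled as a clamped additive polynomial in
chlorophyll-a (quadratic, concave) and water temperature (linear,
increasing): low algal biomass supplies substrate N and favourable
sediment conditions for denitrification, excessive algal decay depletes
oxygen and inhibits the nitrification–denitrification couple, and
warmer water accelerates the microbial rates throughout. The model is
deliberately additive — no Chla×WT interaction — and its negative tails
are clamped at zero because a removal rate cannot be negative.

The shipped default coefficients (β₀ = 500, β₁ = 144, β₂ = −1.2,
β₃ = 120, all kg N km⁻² yr⁻¹ per respective unit) are placeholders on
the published scale of shallow-lake denitrification (a few
g N m⁻² yr⁻¹ for eutrophic lakes, rate maximum near Chl-a ≈ 60 µg L⁻¹).
They are **not** a fitted parameterisation; quantitative applications
must supply site-calibrated values through the `[removal_model]` config
section, which requires all eight fields — partial sections are
rejected rather than silently mixed with defaults.

Applicability is decided by the empirical thermocline regression
log₁₀ THER = 0.185·log₁₀ SA + 0.842 (SA in km², THER in m, logs base
10). Lakes with mean depth above THER are stratified — incomplete
mixing of nutrients, temperature and oxygen — and are excluded from all
downstream stages with an explicit reason. The boundary case (depth
exactly equal to THER) is kept: exclusion is for *exceeding* the
mixed-layer depth.

Where no temperature observation exists, WT falls back to a clamped
linear decline with absolute latitude (28 °C at the equator,
−0.35 °C per degree, floored at 0 °C) — a coarse but monotone,
equator-symmetric stand-in calibrated to the synthetic population.

## Budget conventions

All masses are kg N; concentrations in mg N L⁻¹ convert to storage via
1 mg L⁻¹ = 1 g m⁻³. The river loading coefficient *a* (fraction of
watershed soil N input reaching the lake) is a single scalar per run,
default 0.4, the midpoint of the literature 0.3–0.5 range; a per-lake
column may override it. Negative NANI (net-export watersheds) clamps to
zero inflow: the loading formula assumes a source. *a* multiplies NANI
alone, not deposition. When removal exceeds loading, steady-state
outflow is clamped at zero and the surplus is interpreted as storage
drawdown, which the dynamic model resolves explicitly; this is the
self-purifying regime (removal ratio > 1), a legal and deliberately
represented state. Sediment burial, resuspension and diffusion are
omitted: in shallow mixed lakes these terms are small and tend to
cancel.

## The annual update

The continuous balance dS/dt = dL/dt − dO/dt − dR/dt with proportional
removal d(ln R) = d(ln(L+S)) is discretised as an explicit annual
difference scheme, matching the year-on-year framing of the reduction
scenarios ("b per year, relative to each preceding year"):

1. loading′ = loading·(1−b) (deposition included, per the budget's
   total-loading form; `deposition_constant=true` restricts the
   reduction to the inflow term since management cannot curb direct
   deposition — both conventions are exposed because they are both
   defensible);
2. outflow′ = outflow·(1−b), the same fractional reduction applied
   literally;
3. storage′ = max(0, storage + loading′ − outflow′ − removal), using
   the *previous* year's removal;
4. removal′ = removal·((loading′+storage′)/(loading+storage)) — the
   end-of-step pool in the numerator makes removalₜ/(loadingₜ+storageₜ)
   exactly conserved along the trajectory, the cleanest discrete
   reading of the proportionality. The parenthesisation is deliberate:
   an unchanged pool rescales removal by exactly 1.0 in floating point,
   so an un-clamped steady state (outflow = loading − removal) is a
   bit-exact fixed point at b = 0.

Concentration is evaluated at integer year ends; the goal year is the
first year at or below the target (default 1 mg N L⁻¹). Simulation
proceeds freely past the target storage; thresholds are applied
afterwards. `max_years` defaults to 500, making "not reached"
unambiguous. Degenerate lakes (zero substrate pool) get zero removal.

Two equivalent implementations exist: a scalar per-lake loop (the
reference semantics) and a vectorised form that advances all lakes one
year per numpy operation; the test suite checks their exact agreement.

A consequence worth noting: a self-purifying lake under no action
converges to equilibrium storage S* = L·(1−k)/k with
k = R₀/(L+S₀), so "ratio > 1" guarantees improvement but not
necessarily finite-time goal attainment when the equilibrium
concentration sits at or above the goal. Classification nevertheless
follows the management flow chart (ratio > 1 ⇒ no-action type), which
reflects the decision logic rather than the asymptote.

## Inversion, classification, efficiency

The required reduction for a deadline is the smallest constant b with
goal year ≤ deadline, found by bisection on [0, 1] (tolerance 1e-4 on
b, 32-iteration cap, tie broken toward the smaller feasible b),
exploiting that the goal year is non-increasing in b. Lakes already at
the goal, or drifting to it unaided within the deadline, need b = 0;
lakes missing the deadline even at b = 1 are infeasible (Type III).
The planning horizon defaults to 20 years (a 2030 target from a data
epoch near 2008) and is configurable. The reported
`required_nani_reduction` converts b to a first-year NANI-intensity
decrement, b × NANI, consistent with the per-preceding-year framing.
Type classification: goal met → I; removal ratio strictly above 1 → I
(self-purifying; ratio exactly 1 is a steady state and falls through to
the II/III test); else II when the 20-year inversion is feasible,
else III. The Type III test applies b = 1 under the run's
deposition convention.

Improvement efficiency over a horizon is
(storage₀ − storage_h)/(loading₀ − loading_h), undefined at b = 0; the
pipeline evaluates it under the intermediate (5%) scenario at the
planning horizon. The cumulative improvement curve sorts lakes by
efficiency descending and accumulates normalised reductions; it is
non-decreasing, concave, starts at (0,0), ends at (1,1), and collapses
to the diagonal when efficiencies are homogeneous.

## Monte Carlo uncertainty

Only the quantities with stated error structure are perturbed: Chl-a
(multiplicative mean-one lognormal, CV default 0.2 — strictly positive
and right-skewed, matching a skewed concentration variable), WT
(additive normal, sd default 1 °C) and the loading coefficient *a*
(uniform on its 0.3–0.5 range). NANI and deposition are not perturbed
by default. Each of the 1000 default draws re-runs the full
budget → simulate → invert chain; "95th confidence intervals" are read
as central 95% intervals (2.5/97.5 percentiles). Goal-year draws that
never reach the goal (and infeasible required-b draws) are reported as
a frequency and excluded from percentiles. Draws are deterministic in
(seed, draw index, lake id), so results are bit-reproducible and
order-independent; errors are independent across lakes (no spatial
correlation is modelled).

## The synthetic population

The generator emulates the statistical shape of a global shallow-lake
compilation: lognormal surface area truncated at the 0.1 km² inventory
cutoff (median ≈ 0.5 km²), lognormal mean depth (median ≈ 2.7 m, spread
chosen so a realistic 10–15% minority fails the thermocline screen),
latitude uniform on (−65°, 70°) driving temperature with 2 °C noise,
lognormal Chl-a (median ≈ 12 µg L⁻¹) and deposition (median
≈ 1000 kg N km⁻² yr⁻¹), and a watershed-to-lake area ratio of about
an order of magnitude.

The removal ratio is drawn first — a Bernoulli regime choice
(self-purifying with probability 2049/5768 ≈ 0.355), then a within-
regime draw (1 + lognormal excess for the tail; a Beta body with mean
0.37, floored at 0.02, for net sources) — and watershed loading is
back-solved to realise the drawn ratio exactly (deposition is shrunk to
30% of the target loading in the rare corner where it alone would
exceed it). This guarantees both budget regimes are exercised and the
headline two-regime split holds by construction rather than by chance.
The standing stock is set via a lognormal storage-to-loading scale
(median ≈ 0.2 yr — a residence-time proxy chosen so roughly a third of
lakes exceed the 1 mg L⁻¹ goal and every management type is
populated). Consequences to keep in mind: in this calibrated mode NANI
is *derived*, not normally distributed; the uncalibrated mode
(`target_self_purifying_fraction=None`) draws NANI ~ Normal(mean, sd)
instead and lets the ratio fall where it falls. Concentration is
statistically independent of the removal regime, which real lakes are
not; and no spatial structure beyond the latitude–temperature link is
modelled. Passing tests on this population therefore demonstrate the
*machinery* — mass conservation, monotonicity, inversion consistency,
coverage — not agreement with any real lake inventory.

The validation panel mirrors a decade-long before/after check across
watersheds with declining N input: per watershed a drawn constant
reduction runs the simulator 10 years, "measured" end concentrations
are 3-year epoch averages of model truth plus iid annual observation
noise, and the harness predicts the same epoch average from the start
state. Noise-free, prediction equals truth exactly (R² = 1 by
self-consistency — a plumbing check, not a validation claim); R²
degrades monotonically with noise.

## Numerical and testing notes

Acceptance-style checks that demand exact equality (the b = 0 fixed
point, per-step closure) are exercised with whole-kilogram budgets —
exactly representable in doubles, so the additive identities hold
bit-for-bit — and closure is asserted in the step's own association
order. The scalar and batch simulators, and an independently coded
brute-force loop in the test suite, must agree exactly on shared
inputs. The Monte Carlo coverage check draws the "truth" as one extra
exchangeable draw from the same error spec (400 draws per lake, 500
replicate lakes) so nominal 95% coverage is the expected behaviour.
Problem sizes in the shipped tests and acceptance script (populations
of 600–5768 lakes, 100-year horizons, 400–1000 Monte Carlo draws) were
chosen as comfortable desk-scale runs.

## Known limitations

- Coefficients of the removal model are configuration, not science
  shipped with the package.
- No river-network routing between lakes, no groundwater legacy-N lag,
  no seasonality or stochastic forcing; Chl-a does not feed back on
  removal along trajectories (removal evolves only through the pool
  proportionality).
- The outflow reduction (step 2) follows the same fractional rate as
  loading by convention; re-deriving outflow from the instantaneous
  balance each year would be an alternative discretisation.
- The synthetic generator is a statistical stand-in: it reproduces
  marginal shapes and the two-regime ratio structure, not joint
  dependencies (e.g. residence time vs loading) of real inventories.
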