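# Methods

## Model structure and assumptions

The larva is reduced to two states: dry mass `B_dry` [g] and the
development sum `T_Σ` [h]. Dry mass follows a mass balance on the ingested
feed flux: of each gram ingested, a fraction `k_α_excr` is excreted
undigested, `k_α_assim` is respired to pay for digestion, and the
remainder is available for growth and maintenance. Ingestion and the
combined maturity-plus-maintenance drain are both taken proportional to
body mass (specific rates `k_inges`, `k_maint` [g g⁻¹ s⁻¹]), which makes
the unregulated system a von-Bertalanffy-type growth law with exponent 1.
Maturity and maintenance are merged into one flux because both run
throughout the larval stage and cannot be separated by dry-mass
measurements alone.

Development is not size-dependent in BSF (larvae complete development even
when far below maximal size), so stage is tracked by the development sum:
apparent age accrues at up to one hour per real hour (`k_dev_ts` = 1/3600
h s⁻¹ by default; the shipped estimates do not include a value, and
apparent age cannot outrun real time), scaled by the development regulator
`r_dev ∈ [0, 1]`. This generalizes degree-day accounting from temperature
alone to temperature, feed, moisture and airflow.

Three stage milestones partition the life cycle: feeding is maximal before
`k_TΣ1`, ramps to zero at `k_TΣ2` (mouth-part degeneration before the
non-feeding prepupal instar), and the maturity-maintenance drain stops at
`k_TΣ3` (prepupa → pupa). Pupal metamorphosis consumes reserves at some
nonzero rate, but that stage is outside this model: after `k_TΣ3` the
simulated mass is constant. Ingestion is additionally throttled by
`1 − B_dry/k_B_asy` (floored at zero for masses beyond the asymptote,
where negative assimilation would be meaningless and destabilizing).

## Environmental factors and normalization

Each environmental factor acts through a dedicated response curve:
temperature through either a boundary-corrected Arrhenius law or a
modified Logan-10 curve whose high-temperature branch decays to zero
rather than going negative (Logan-10 is the default regulator — it fits
the aggregated temperature sweeps at least as well with one parameter
fewer); feed density through two Monod instances (development:
`k_B_half_dm`; growth: `k_B_half_gm`, units g dry feed d⁻¹ per larva);
moisture through the product of an ingestion ramp (zero below
`k_W_med_C1` ≈ 0.33, maximal above `k_W_med_C2` ≈ 0.69) and a respiration
shut-off (declining above `k_W_med_C3` ≈ 0.76 to zero at
`k_W_med_crit` ≈ 0.83, where oxygen diffusion into the wet substrate
ceases); airflow through Monod saturation by default (a logistic
alternative is provided exactly as conventionally parameterized, which
requires a negative transition parameter for an increasing response — it
ships without default values and is never silently sign-corrected).

Several shipped maxima are normalized (dimensionless ≈ 1) because fitting
operated on rates scaled by each dataset's observed maximum. The combined
regulators therefore always divide each factor by its own maximum, so the
normalization never leaks into the dynamics. For Logan-10 and Monod the
maximum is the `r_max` parameter itself; the boundary-corrected Arrhenius
curve peaks above its reference rate, so its normalizer is the numerical
maximum of the curve over [−20, 80] °C (computed once per profile by
bounded scalar minimization and cached, then clipped to [0, 1]).

A documented unit ambiguity: the airflow half-saturation is quoted per kg
of substrate while the airflow state is an absolute flow; only the ratio
`A/(A + k_half)` enters the model, so both readings are usable as long as
caller and profile agree on the convention.

## Switching and smoothing

All piecewise cases (the two stage switches and both moisture ramps) are
replaced inside the ODE by logistic functions — biology transitions
gradually, and the solver needs a smooth right-hand side. The convention
is: midpoint at the ramp center, slope `4/width`, which matches the linear
ramp's slope and value at its midpoint exactly and bounds the deviation by
1/(1+e²) ≈ 0.119 at the ramp endpoints and 1/(1+e⁶) ≈ 0.0025 one full
ramp-width outside. The instantaneous maturity switch at `k_TΣ3` has no
intrinsic width; it gets a configurable smoothing width `w_mat` (default
10 h) — consequently the simulated mass settles to its terminal plateau a
few multiples of `w_mat` after the `k_TΣ3` crossing, not instantaneously.
The smoothed assimilation switch retains the multiplicative
size-potential factor (dropping it, as a bare logistic would, loses the
asymptotic-size throttle). Piecewise forms remain available
(`smooth=False`) for unit-level verification only. All exponentials are
clamped at ±700 before evaluation so every response is finite for any
physically representable input.

## Simulation

Time runs internally in seconds (the specific rates are per second); the
public API is in hours. Integration uses adaptive Runge–Kutta (RK45) at
rtol 1e-8 / atol 1e-12 g — the regulator products span orders of magnitude
near switches — and proceeds segment-by-segment between schedule
breakpoints, since environments are piecewise constant under the default
zero-order hold (experiments hold conditions between interventions;
linear interpolation is optional). Under this setup the simulated
trajectory reproduces the closed-form exponential solution (constant unit
regulators) to ≈2×10⁻⁷ relative over 200 h, and halving the tolerances
moves the final mass by ≈1×10⁻⁷ relative. Milestone crossings of the
development sum are located by the solver's root finder on dense output;
`detect_stage_events` re-derives them from a recorded trajectory via
monotone (PCHIP) interpolation and Brent root bracketing, well below
0.01 h error on any reasonable grid.

### Quasi-equilibrium growth and the location of the mass peak

With the shipped rates, `ε_inges·k_inges − k_maint ≈ 0.44 h⁻¹` at unit
regulators: growth is fast relative to development. Under constant
near-optimal conditions the mass therefore reaches a quasi-equilibrium
`B* = k_B_asy·(1 − k_maint·E_mat/(ε_inges·k_inges·E_assim))` ≈ 0.109 g
within roughly 100 h, while the development sum needs 320–430 h to reach
the milestones. Two consequences worth knowing:

1. **The trajectory's true maximum precedes the first milestone.** From
   ≈100 h the mass tracks a plateau that declines only through the far
   tail of the smoothed feeding switch (nanograms per hour); the argmax of
   the simulated series lands at the start of that plateau, and the
   clearly visible maturation drop develops across the feeding-shutdown
   window. Peak detection reports the plain argmax; on the plateau it is
   resolution-limited by solver accuracy (~1e-9 relative).
2. **The plateau mass is feed-independent.** The normalized feed-growth
   factor multiplies both the assimilation and the maturity-maintenance
   regulator, so it cancels from `B*`. Feeding level controls how fast the
   plateau is approached and how fast development proceeds — not the
   plateau itself. Mass monotonicity in feed is therefore strict during
   the rise and non-strict (equality at equilibrium) for the peak.

The flux partition always uses the budget identity
`φ_eff = (1 − k_α_excr − k_α_assim)·φ_ing`, so ingestion is conserved
exactly. The shipped estimates carry an internal inconsistency: the quoted
digestion efficiency (0.79) differs from the budget-derived value
(1 − 0.5762 − 0.2135 = 0.2103). The profile stores `ε_inges` as an
independent parameter defaulting to 0.79 and used in the growth equation;
`eps_mode='derived'` switches to the strict budget value.

## Parameter estimation

Static rate models are fit by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective, tolerances
1e-13) from Latin-hypercube-stratified starting points within the bounds
box (default 32 starts; seeded, hence bit-reproducible). Default bounds
are generous physical ranges (e.g. boundary temperatures within
rearing-relevant spans, thresholds inside [0, 1]); the best converged
start wins. The workflow mirrors how heterogeneous literature sweeps are
combined: convert development times to rates (reciprocals), normalize each
dataset by its observed maximum (removing feed-type and assay scale),
pool the normalized sets probing the same factor (pointwise averaging is
available; pooling differs only in implied weighting), fit, then rescale
maximum-rate parameters by the observed maximum.

Two exact reparameterization redundancies are handled by convention
rather than estimation: the Arrhenius pair (`k_r_ref_T`, `k_T_ref`)
enters only through `k_r_ref_T·exp(k_T_A/k_T_ref)`, and the Logan-10 pair
(`k_r_base_T`, `k_T_base`) only through `k_γ·exp(k_ρT·k_T_base)`. The
reference temperature and the base temperature are therefore held fixed
during fitting (defaults: the shipped profile values; both are
conventions directly readable from data, not estimable quantities).

Identifiability under noise is model-dependent. At the synthetic design
used for recovery testing (n = 50, Gaussian noise with σ = 5% of the
response maximum), the asymptotic (Cramér–Rao) standard deviations are
≈16% for the Logan-10 boundary width `k_ΔT` and ≈52% for the Arrhenius
lower-boundary temperature `k_T_AL`: those parameters shape the response
only in narrow temperature windows where the signal is comparable to the
noise, and no estimator can pin them to 10% at this noise level. The
recovery suite documents this: Monod, moisture, and airflow parameters
recover within 10% in ≥90% of replicates; the thermal boundary
parameters do not.

Dynamic fitting simulates every candidate parameter vector through the
full ODE for each trajectory (dry mass is the only observed state; the
development sum is latent) and minimizes the joint unweighted residual.
The parameter mask uses flat canonical symbols mapped onto the nested
profile; candidates violating ordering invariants or failing to integrate
contribute a large constant residual, and a start that fails at its
initial point is marked non-converged while the others continue. Default
bounds are a factor-of-20 box around the profile value; multistart
default is 8 (the trajectory objectives are smooth and well identified,
and each evaluation costs an ODE solve). `calibrate_subset` wraps this to
re-estimate, e.g., the two feed half-saturations on a pair of
trajectories when the feed type changes, returning a renamed profile with
all untouched parameters carried over bit-identically.

R² is the standard coefficient of determination `1 − SS_res/SS_tot`
about the observed mean; it may be negative for poor fits and is
undefined (an error) for zero-variance observations.

## Synthetic data

The generators emulate the *structure* of the calibration literature —
temperature sweeps of development rate, feed-density sweeps of development
and growth rate, moisture and airflow sweeps, and dry-mass trajectories
at several feeding levels — by sampling the model itself plus observation
noise, recording the generating parameters as ground truth. Default
designs follow the source experiments: linear grids for temperature
(10–42 °C), moisture (0.10–0.95) and airflow (0–3 l min⁻¹), and a
geometric grid for feed density (0.002–0.2 g d⁻¹ per larva), because
feeding-rate experiments use multiplicative dose series concentrated at
low rates — which is also what makes a half-saturation of ~0.005 g d⁻¹
measurable at all. Noise defaults to Gaussian with σ = 5% of the response
maximum, truncated at zero (a fraction-of-maximum model matching the
normalized fitting workflow); a median-preserving lognormal alternative is
provided. Trajectories start at the 2 mg experimental neonate weight and
are sampled twice daily by default.

What passing recovery tests do and do not show: they verify that the
estimation machinery inverts the model correctly under the model's own
noise assumptions. Real rearing data add model error (substrate depletion
and microbial dynamics, population heterogeneity, measurement batching)
that no synthetic test here represents; the generators intentionally do
not emulate those.

## Known limitations

- Substrate feed, water and gas states are exogenous drivers; their own
  balances (depletion, evaporation, O₂/CO₂, metabolic heat) are not
  modelled. The flux outputs let callers do substrate bookkeeping.
- Wet mass, population counts and mortality are out of scope; the model
  tracks one representative larva's dry mass.
- The post-`k_TΣ3` pupal stage is represented as inert (constant mass).
- The logistic airflow model ships without fitted defaults and with its
  as-printed sign convention; the Monod airflow form is the default.
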