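# hermetia

A dynamic growth and development model of *Hermetia illucens* (black
soldier fly, BSF) larvae, for people who rear them — as aquaculture and
livestock feed, or as bio-waste converters — and need to predict how dry
mass and developmental stage evolve under controllable rearing conditions:
substrate temperature, feeding rate, substrate moisture, and airflow.

The package provides

- **environmental rate functions**: a boundary-corrected Arrhenius law and
  a modified Logan-10 thermal performance curve (non-negative above the
  lethal temperature), Monod (type-II) saturation in feed density and in
  airflow, a logistic airflow alternative, and a piecewise moisture
  response combining an ingestion ramp with a high-moisture respiration
  shut-off;
- **a two-state ODE simulator** for larval dry mass and development sum
  (apparent age), with stage-dependent regulation, smooth switching, flux
  bookkeeping, and milestone-event detection;
- **the parameter-estimation workflow** used to calibrate it: per-dataset
  normalization, grouping, multi-start bounded nonlinear least squares for
  the static rate models and for the dynamic model, subset recalibration,
  and R² reporting;
- **synthetic-data generators** that emulate the structure of the
  literature datasets the model was calibrated on (temperature, feed,
  moisture and airflow sweeps; dry-mass trajectories at several feeding
  levels), with exact ground truth for recovery testing;
- a **CLI** (`hermetia evaluate | simulate | fit | calibrate | generate`).

## The model

Larval dry mass `B_dry` [g] and the development sum `T_Σ` [h] (hours of
optimal growing conditions accumulated — a multi-factor generalization of
degree-days) obey

    dB_dry/dt = ε_inges · r_assim · k_inges · B_dry − r_mat · k_maint · B_dry
    dT_Σ/dt   = r_dev · k_dev_ts

where `k_inges` and `k_maint` are the specific maximum ingestion and
maturity-plus-maintenance rates [g g⁻¹ s⁻¹] and `ε_inges` the digestion
efficiency. The regulators are products of normalized factors in [0, 1]:

    r_assim = r_B_assim(T_Σ, B_dry) · (r_T/r_T,max) · (r_F,grw/r_max,gm) · (r_W/r_max,W) · (r_A/r_max,A)
    r_mat   = r_B_mat(T_Σ) · (r_T/r_T,max) · (r_F,grw/r_max,gm) · (r_A/r_max,A)
    r_dev   = (r_T/r_T,max) · (r_F,dev/r_max,dm) · (r_W/r_max,W) · (r_A/r_max,A)

`r_B_assim` throttles ingestion by the asymptotic size
(`1 − B_dry/k_B_asy`, von-Bertalanffy form) and shuts feeding down across
the development window [`k_TΣ1`, `k_TΣ2`]; `r_B_mat` stops the
maturity-maintenance drain at `k_TΣ3`, the end of larval development. All
switches are implemented as logistic functions (slope 4/width) so the ODE
right-hand side stays smooth. Two parameter profiles ship with the
package: `table3_original` and `table3_recalibrated_D1D5` (feed
half-saturations re-estimated on a trajectory subset after a feed-type
change).

## Worked example

Simulate a larva from 2 mg under near-optimal constant conditions and read
off the stage events:

```python
import hermetia as hm

profile = hm.load_profile("table3_recalibrated_D1D5")
env = hm.EnvironmentState(T_med=31.0, B_feed=0.2, W_med_pct=0.72, A_air=3.0)
schedule = hm.EnvironmentSchedule.constant(env)
traj = hm.simulate(hm.LarvaState(B_dry=0.002), schedule, profile, t_end_h=650.0)
print(hm.detect_stage_events(traj, profile.stage).to_string(index=False))
```

prints

```
           event      value
k_TS1_crossing_h 337.864921
k_TS2_crossing_h 382.774212
k_TS3_crossing_h 428.908957
     peak_time_h 124.500000
    peak_B_dry_g   0.109283
```

i.e. the larva grows to its quasi-equilibrium mass of ≈0.109 g (just
below the asymptote 0.115 g, held down by maintenance), feeding starts to
cease at ≈338 h, ends at ≈383 h, and development completes at ≈429 h,
after which the dry mass — reduced by the maturation drop — stays
constant. The full time courses (states, regulators, all mass fluxes)
are in `traj.to_frame()`.

Fitting a feed-density growth-rate sweep with the normalization workflow:

```python
from hermetia import fit_static, normalize_dataset, rescale_to_observed
from hermetia.synthetic import ScenarioSpec, NoiseSpec, generate_response_dataset

ds = generate_response_dataset(
    ScenarioSpec(profile=profile, noise=NoiseSpec("gaussian", 0.05, seed=0)),
    "monod_grw",
)
norm = normalize_dataset(ds)
result = rescale_to_observed(
    fit_static(norm, "monod_grw", n_starts=32, seed=0),
    max_rate=float(ds.response.max()),
)
print(result.report())
```

```
model: monod_grw
param r_max: 1.98935898676825
param k_half: 0.00543354683038035
rss: 0.047243816316484694
r_squared: 0.9696285831683349
n_obs: 30
n_starts: 32
best_start: 19
n_converged: 32
```

— the generating values were `r_max = 2`, `k_half = 0.00532`, recovered
here from 5%-noise data to within ~2%.

The same operations are available from the shell, e.g.

```sh
hermetia simulate --temp 31 --feed 0.2 --moisture 0.72 --airflow 3 \
    --t-end 650 --out run
hermetia evaluate --model monod_dev --at 0.0049
```

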