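# neurovuln

Hybrid agent-based / ODE simulation of how aging nematode neurons become
vulnerable to oxidative stress and tau accumulation.

Neurodegeneration in aging (and in tauopathies such as Alzheimer's disease)
emerges from the interplay of rising reactive oxygen species (ROS), tau
aggregation, mitochondrial decline, and the stress responses that buffer
them. `neurovuln` models a population of *C. elegans*-style neurons, each
carrying:

* a continuous molecular network — ROS `R`, tau load `T`, and nine
  Hill-driven response activities in [0, 1] (hsp-60 / UPR^mt, BiP and p-PERK /
  UPR^ER, skn-1, daf-16, sod-2, bec-1, mTOR, pink-1), with age-declining
  capacities and chronic-stress repression:

      dA_i/dt = (drive_i(network) · capacity_i(t) − A_i) / τ_i
      dR/dt   = (ρ0 + ρ_age t)(1 + ρ_m f_d + ρ_T T/(T+K)) − R(δ0 + Σ w_i A_i)
      dT/dt   = σ m_tau (1 + β·hill(R)) − T(κ0 + w_b A_bec1 + w_u A_BiP)

* a pool of up to 100 stochastic mitochondrion agents (ROS- and tau-driven
  damage, pink-1×bec-1 mitophagy, age-declining biogenesis), and
* a cell-fate machine: RESILIENT → MT-/ER-COMPROMISED (UPR activity < 0.5) →
  DUAL-COMPROMISED → VULNERABLE (plus oxidative & proteotoxic insults) →
  rate-dependent DEATH.

The UPR hubs carry positive self-feedback, so their dose–response to
sustained ROS is bistable: late-life collapse of stress-response capacity is
hysteretic and effectively irreversible. Scenario perturbations double tau
aggregation ("pro-aggregating tau"), knock down or overexpress nodes
(e.g. skn-1 at 10% / 150%), and combine. A one-at-a-time sensitivity scan
(5% parameter reductions, normalized coefficients, |SC| ≥ 1 = significant)
identifies the controlling constants. See `docs/methods.md` for the full
model description and its limitations.

## Worked example

Recompute the headline population metrics of the calibrated defaults at a
small scale (200 cells, 2 replicate seeds; ~1 minute):

```
$ neurovuln calibrate --n-cells 200 --n-replicates 2 --seed 1 --out results/
uprmt_below_half_day20_pct: 23.657
uprer_below_half_day20_pct: 29.023
cumulative_loss_day19_pct: 6.000
first_vulnerable_day: 15.500
tau_cumulative_loss_day14_pct: 5.000
tau_resilient_day9_pct: 2.000
```

Reading: at the end of life (day 20 of adulthood) about a quarter of
surviving cells have mitochondrial UPR activity below the 0.5 compromise
threshold and about 30% have ER UPR activity below it; fully vulnerable
cells first appear in mid-to-late life and ~5–6% of the population has died
by day 19. Under doubled tau aggregation the same 5% loss is reached five
days earlier (day 14), and by day 9 essentially no resilient cells remain
(the 2% here is small-sample granularity at 200 cells). Mapping the 20-day
nematode lifespan linearly onto 100 human years
(`neurovuln.extrapolate_to_human_years`) places vulnerability onset around
60 years and 5% neuronal loss around 95 years.

Other entry points (all accept `--config`, `--seed`, `--out`):

```
neurovuln run          # one population run -> trajectories, survival, CSVs
neurovuln replicates   # replicate-averaged summaries
neurovuln signature    # fold-change molecular signature vs day 0 (M/L columns)
neurovuln sweep-ros    # clamped-ROS dose-response, hysteresis branches,
                       # late-life ROS-removal trajectory
neurovuln sensitivity  # OAT sensitivity scan (CSV of SCs and categories)
neurovuln topology     # regulatory edge list as CSV
```

A YAML config selects scenarios and overrides parameters:

```yaml
scenario:
  scenario_name: tau      # or skn1-ablation, uprer-deficient, tau-skn1-oe, ...
  n_cells: 500
  seed: 7
parameters:
  death_hazard: 0.5
```

As a library:

```python
from neurovuln import scenario_config, run_simulation, survival_curve

traj = run_simulation(scenario_config("tau", n_cells=300, seed=1))
print(survival_curve(traj).iloc[-1])   # % surviving at day 20
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-simulates both headline scenarios from scratch (500 cells × 10 replicate
seeds each, 20 days, dt = 0.005) and writes the five summary quantities —
the two day-20 UPR threshold fractions, the day-19 cumulative loss, the
first day with vulnerable cells (normal aging), and the day-14 cumulative
loss (tau scenario) — as JSON. `scripts/calibrate.py` documents and
re-verifies the calibration that produced the shipped defaults.
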