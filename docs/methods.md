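# Methods

`neurovuln` simulates a population of aging nematode neurons as a hybrid of
continuous per-cell dynamics (a Hill-function stress-response network) and
discrete stochastic events (mitochondrial damage/turnover, cell-fate
transitions, death). This note documents the model, its assumptions, the
calibration, and what the shipped defaults do and do not establish.

## The per-cell continuous network

Each cell carries a ROS level `R`, a tau aggregate load `T`, and nine
normalized response activities `A_i ∈ [0,1]` (hsp-60, BiP, p-PERK, skn-1,
daf-16, sod-2, bec-1, mTOR, pink-1). Every activity relaxes toward a target

    dA_i/dt = (target_i − A_i) / τ_i
    target_i = min(drive_i, 1) · stress_i · exp(−λ_i t) · scale_i,  clipped to [0,1]

where `drive_i` sums weighted activation/repression Hill terms on the node's
inputs, `stress_i` collects chronic-stress repression factors, `exp(−λ_i t)`
is an age-declining capacity, and `scale_i` is the scenario expression scale.
Because targets live in [0,1], activities cannot leave the unit interval.

ROS is modeled as a fast species (turnover ≈ 0.2 days):

    dR/dt = (ρ0 + ρ_age·t) · (1 + ρ_m·f_d + ρ_T·T/(T+K_sat)) − R·(δ0 + Σ w_i A_i)

with `f_d` the cell's damaged mitochondrial fraction and the clearance sum
over sod-2/skn-1/daf-16. Two deliberate choices here:

* **Multiplicative stress amplification.** Damaged mitochondria and tau
  amplify the age-dependent production term rather than adding to it. With
  additive stressors, reducing the age-production or basal-clearance constant
  by 5% can never move ROS by ≥ 5% at day 5 (the age term owns too small a
  share), i.e. the one-at-a-time sensitivity scan could not classify those
  parameters as significant early in life. Saturation of the tau term
  (`K_sat`) keeps the tau-exacerbated scenario bounded.
* **Fast turnover.** With slow ROS clearance the production ramp outpaces the
  pool (lag ≈ 1/clearance), which caps the clearance elasticity at day 5
  around 0.7 regardless of parameter shares. Fast turnover makes the pool
  quasi-static, which is also the physically sensible regime.

Tau accumulates with a ROS-boosted production and is cleared by autophagy
(bec-1) and the UPR^ER (BiP):

    dT/dt = σ_T · m_tau · (1 + β·hill(R)) − T · (κ0 + w_b·A_bec1 + w_u·A_BiP)

`m_tau` is exactly 1 in normal aging and 2 in the tau-exacerbated scenario
("100% increase in tau aggregation"). The BiP term creates the central
positive feedback of the tau scenario: once BiP collapses, tau clearance
drops and the load accelerates.

## The UPR hubs: bistability and collapse

`uprmt_hsp60` and `uprer_bip` carry positive self-feedback (Hill n = 6 and 4)
and chronic-stress repression of their capacity. The steady-state activity of
hsp-60 versus clamped ROS therefore folds: a resilient high branch and a
compromised low branch (< 0.5) coexist over a clamp window (default
parameterization: maximal branch gap ≈ 0.5–0.6). A cell carried past the fold
does not recover when ROS is removed late in life (`neurovuln sweep-ros`
reports both branches and the removal trajectory; the removal fraction
defaults to 0.5 and is configurable).

Chronic-stress channels, chosen so each scenario collapses the right
response at the right time:

* **BiP** is repressed by chronic ROS, by chronic tau load, and by the
  *aggregation-flux fold-increase over basal*, `m_tau·(1+β·hill(R))`. The
  flux channel senses how hard misfolded protein is being produced relative
  to the chaperone capacity the cell was built with; crucially the scenario
  multiplier enters it exactly (it is not subject to cell-to-cell parameter
  scatter), which is what lets the doubled-aggregation scenario push
  essentially every cell below the 0.5 threshold by day ~9 while normal aging
  only takes the most susceptible ~30% below it by day 20.
* **hsp-60** is repressed by chronic ROS and (weakly) tau load, and its
  capacity additionally requires UPR^ER support: once a cell's BiP activity
  falls below ~0.33, hsp-60 capacity is dragged toward a floor of 0.70. This
  encodes the observation that ER dysregulation begets mitochondrial
  deficits, and it is what makes an hsp-60 knockout nearly neutral in normal
  aging (cells that lose BiP lose hsp-60 shortly after anyway).
* **p-PERK** shares BiP's inputs with a slower relaxation time and no
  chronic collapse; it reports sustained translational ER stress but does not
  enter the phenotype classification.

## Mitochondrion agent pools

Each cell owns up to 100 two-state (healthy/damaged) mitochondria. Per step,
healthy organelles are damaged with hazard
`k_dam·hill(R) + k_tau·hill(T)·(1 − 0.6·A_hsp60)` — an oxidative term plus a
proteotoxic term that hsp-60 shields against — damaged ones are removed by
mitophagy with hazard `k_mito·A_pink1·A_bec1`, and removed slots are refilled
healthy with an age-declining biogenesis probability `exp(−λ_bio·t)`. Because
organelles are exchangeable, the per-organelle events are sampled exactly
with batched binomial draws. The damaged fraction feeds back into ROS
production and the hsp-60 drive. The hsp-60 shield acting on the
*proteotoxic* term only is what makes the UPR^mt knockout costly under tau
but nearly free in normal aging, where that term is negligible.

## Phenotypes and death

A cell is mitochondria-compromised while `A_hsp60 < 0.5` and ER-compromised
while `A_BiP < 0.5`; the flags are re-evaluated each step (recovery is
dynamically rare because of hysteresis, but not forbidden). When both flags
hold and the oxidative and proteotoxic loads exceed thresholds
(`R` above ~1.66 and `T` above ~0.30, thresholds sampled per cell), the cell
enters the absorbing VULNERABLE state and from there dies with constant
hazard 0.70/day. All agents are initialized RESILIENT at their own basal
fixed point with intact pools. Deaths remove cells from all population
averages.

## Heterogeneity and reproducibility

Every non-structural positive parameter of every cell is multiplied by an
independent Gaussian factor (mean 1, sd = cv, default cv = 0.10) truncated to
[1−3cv, 1+3cv]. Hill coefficients, expression scales and the scenario
multiplier are structural and never sampled. Parameter draws come from
per-cell `SeedSequence`-spawned streams; mitochondrial and death events use
one vectorized stream in fixed cell order. A run is bit-reproducible from its
master seed.

Integration is fixed-step RK4 (default dt = 0.005 day) with operator
splitting: ODE substep with the damaged fraction frozen, then the stochastic
substep. Halving dt moves day-20 population means by well under 1%.

## Calibration

The rate constants are not identifiable from qualitative constraints alone,
so ~6 late-life constants (chronic-stress Ks of the two UPR hubs, capacity decline rates, the
vulnerability ROS threshold, death hazard) were searched once against the
population targets — ≈26% of surviving cells with hsp-60 < 0.5 and ≈32% with
BiP < 0.5 at day 20, ≈5% loss by day 19 (normal), vulnerability onset after
day 12, ≈5% loss by day 14 (tau) — and frozen into `NetworkParameters` /
`data/default_params.yaml`. `scripts/calibrate.py` re-verifies the frozen
point and documents the search procedure (`--polish`).

## Known limitations

* **Tau-scenario resilience tail.** "No resilient cells after day 9" holds to
  integer-percent precision, not absolutely: ~0.5–1% of cells (the jointly
  most protected draws under the ±30% truncated heterogeneity) cross during
  days 9–11.5. With independent per-parameter scatter this tail is
  structural; the acceptance test tolerates < 1.5%.
* **Day-19 sensitivity bias.** The scan's output is the mean ROS of *living*
  cells; by day 19 deaths (~3–5%) have removed the highest-ROS cells, which
  biases day-19 coefficients toward zero by ~0.1–0.2. The clearance parameter
  stays above the significance line; the age-production parameter sits on it
  (death-free value ≈ 1.1–1.2).
* Phenotype-onset ordering (mitochondrial compromise early, ER later) is
  reproduced qualitatively through an early low-branch subpopulation, but the
  mid-life gap between the two compromised fractions is narrow.
* No spatial structure, cell–cell signaling, neuron/astrocyte distinction,
  inflammation or DNA-damage response; single ROS pool; two-state organelles.
* The synthetic world ships no experimental fold-change values; the
  correlation analysis (`correlation_r2`, identity-line convention by
  default, OLS optional) consumes a user-supplied CSV.

A green acceptance suite establishes that the *calibrated defaults* reproduce
the headline population statistics and orderings at desk scale — not that these
reconstructed rate laws are the only ones that could do so.
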