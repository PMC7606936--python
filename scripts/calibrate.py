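"""Calibration of the default parameterization.

The supplementary parameter tables of the original model are not available,
so a handful of late-life stress constants were fitted once against the
population targets (UPR^mt / UPR^ER fractions below 0.5 at day 20, ~5% loss
at day 19 normal / day 14 tau, vulnerability onset after day 12) and frozen
into ``NetworkParameters`` and ``data/default_params.yaml``.

Default invocation verifies the frozen point (prints metrics vs targets).
``--polish N`` runs N rounds of coordinate search over the free calibration
knobs and writes the refined parameter file to --out; this is the procedure
that produced the shipped defaults.

Usage:
    python scripts/calibrate.py [--n-cells 300] [--n-replicates 3]
                                [--polish 0] [--out params.yaml] [--seed 0]
"""

from __future__ import annotations

import argparse
import dataclasses

from neurovuln.calibration import calibration_metrics
from neurovuln.config import save_params
from neurovuln.network import NetworkParameters

TARGETS = {
    "uprmt_below_half_day20_pct": (26.0, 5.0),
    "uprer_below_half_day20_pct": (32.0, 5.0),
    "cumulative_loss_day19_pct": (5.0, 2.0),
    "tau_cumulative_loss_day14_pct": (5.0, 2.0),
}
ONSET_KEY = "first_vulnerable_day"
ONSET_MIN = 12.0

#: the free knobs of the calibration (all other constants stay fixed)
KNOBS = [
    "uprmt_ros_stress_K",
    "uprer_flux_stress_K",
    "vuln_ros_threshold",
    "death_hazard",
    "uprmt_capacity_decline",
    "uprer_capacity_decline",
]


def loss(metrics: dict) -> float:
    z = 0.0
    for key, (target, tol) in TARGETS.items():
        z += ((metrics[key] - target) / tol) ** 2
    if metrics[ONSET_KEY] < ONSET_MIN:
        z += ((ONSET_MIN - metrics[ONSET_KEY]) / 0.5) ** 2
    return z


def report(metrics: dict) -> None:
    for key, (target, tol) in TARGETS.items():
        ok = abs(metrics[key] - target) <= tol
        print(f"  {key}: {metrics[key]:6.2f}  target {target} +- {tol}  "
              f"{'OK' if ok else 'OFF'}")
    onset = metrics[ONSET_KEY]
    print(f"  {ONSET_KEY}: {onset:6.2f}  must be >= {ONSET_MIN}  "
          f"{'OK' if onset >= ONSET_MIN else 'OFF'}")
    print(f"  tau resilient fraction at day 9: {metrics['tau_resilient_day9_pct']:.2f}%")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-cells", type=int, default=300)
    ap.add_argument("--n-replicates", type=int, default=3)
    ap.add_argument("--polish", type=int, default=0, help="coordinate-search rounds")
    ap.add_argument("--step", type=float, default=0.04, help="relative step size")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default=None, help="write refined parameter YAML here")
    args = ap.parse_args()

    params = NetworkParameters()

    def evaluate(p):
        return calibration_metrics(
            p, n_cells=args.n_cells, n_replicates=args.n_replicates,
            dt=0.01, seed=args.seed,
        )

    metrics = evaluate(params)
    best = loss(metrics)
    print("frozen defaults:")
    report(metrics)

    for round_ in range(args.polish):
        improved = False
        for knob in KNOBS:
            for direction in (+1, -1):
                trial = dataclasses.replace(
                    params, **{knob: getattr(params, knob) * (1 + direction * args.step)}
                )
                m = evaluate(trial)
                z = loss(m)
                if z < best:
                    best, params, metrics, improved = z, trial, m, True
                    print(f"[round {round_}] {knob} {direction:+d} -> loss {z:.3f}")
        if not improved:
            break

    if args.polish:
        print("after polish:")
        report(metrics)
    if args.out:
        save_params(params, args.out)
        print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
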