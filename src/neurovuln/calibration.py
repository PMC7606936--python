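"""Population metrics that the shipped default calibration targets.

These are the headline numbers of the model: the fractions of surviving
cells with compromised UPR activities at the end of life, the cumulative
losses in the normal and tau-exacerbated scenarios, and the first appearance
of fully vulnerable cells.  ``scripts/calibrate.py`` used these to fix the
default parameterization once; the acceptance machinery recomputes them.
"""

from __future__ import annotations

import numpy as np

from .engine import run_simulation
from .network import NetworkParameters, scenario_config
from .population import Phenotype

__all__ = ["calibration_metrics", "scenario_metrics"]


def scenario_metrics(
    scenario: str,
    params: NetworkParameters,
    *,
    n_cells: int,
    dt: float,
    seed: int,
    duration: float = 20.0,
) -> dict:
    """Single-run summary metrics for one scenario."""
    cfg = scenario_config(scenario, n_cells=n_cells, dt=dt, seed=seed, duration=duration)
    traj = run_simulation(cfg, params)
    pc = traj.phenotype_counts
    final_day = traj.per_cell.time.max()
    final = traj.per_cell[traj.per_cell.time == final_day]
    living = final[final.phenotype < int(Phenotype.DEAD)]

    vuln_or_dead = pc["VULNERABLE"] + pc["DEAD"]
    nonzero = vuln_or_dead.index[vuln_or_dead > 0]
    first_vuln = float(nonzero[0]) if len(nonzero) else float("inf")

    def dead_pct(day):
        return 100.0 * float(pc["DEAD"].loc[day]) / cfg.n_cells

    day9 = traj.per_cell[traj.per_cell.time == 9.0]
    return {
        "uprmt_below_half_day20_pct": 100.0 * float((living.uprmt_hsp60 < 0.5).mean()),
        "uprer_below_half_day20_pct": 100.0 * float((living.uprer_bip < 0.5).mean()),
        "cumulative_loss_day14_pct": dead_pct(14.0),
        "cumulative_loss_day19_pct": dead_pct(19.0),
        "cumulative_loss_day20_pct": dead_pct(float(final_day)),
        "first_vulnerable_day": first_vuln,
        "resilient_day9_pct": 100.0 * float(pc["RESILIENT"].loc[9.0]) / cfg.n_cells,
        "n_cells": cfg.n_cells,
    }


def calibration_metrics(
    params: NetworkParameters | None = None,
    *,
    n_cells: int = 500,
    n_replicates: int = 10,
    dt: float = 0.005,
    seed: int = 0,
) -> dict:
    """Replicate-averaged calibration metrics for both headline scenarios.

    Normal aging contributes the day-20 UPR threshold fractions, the day-19
    loss, and the first-vulnerable day; the tau scenario contributes the
    day-14 loss and the day-9 resilient fraction.  Replicate seeds are
    ``seed .. seed + n_replicates - 1``.
    """
    params = params or NetworkParameters()
    seeds = [int(seed) + i for i in range(n_replicates)]

    def averaged(scenario, keys):
        rows = [
            scenario_metrics(scenario, params, n_cells=n_cells, dt=dt, seed=s)
            for s in seeds
        ]
        return {k: float(np.mean([r[k] for r in rows])) for k in keys}

    normal = averaged(
        "normal",
        ["uprmt_below_half_day20_pct", "uprer_below_half_day20_pct",
         "cumulative_loss_day19_pct", "first_vulnerable_day"],
    )
    tau = averaged(
        "tau",
        ["cumulative_loss_day14_pct", "resilient_day9_pct"],
    )
    return {
        "uprmt_below_half_day20_pct": normal["uprmt_below_half_day20_pct"],
        "uprer_below_half_day20_pct": normal["uprer_below_half_day20_pct"],
        "cumulative_loss_day19_pct": normal["cumulative_loss_day19_pct"],
        "first_vulnerable_day": normal["first_vulnerable_day"],
        "tau_cumulative_loss_day14_pct": tau["cumulative_loss_day14_pct"],
        "tau_resilient_day9_pct": tau["resilient_day9_pct"],
        "n_cells": n_cells,
        "n_replicates": n_replicates,
    }
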