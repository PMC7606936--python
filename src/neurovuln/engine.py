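"""Time-stepped co-simulation of the cell population.

Operator splitting per fixed step ``dt``: a classical 4th-order Runge–Kutta
substep for each living cell's continuous network (with the damaged
mitochondrial fraction held constant), then the stochastic substep
(mitochondrial damage/mitophagy/biogenesis events, phenotype re-evaluation,
death draws).  All cells advance together on vectorized arrays; randomness
comes from per-cell streams for parameter sampling plus one vectorized event
stream, all derived from the master seed, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network as net
from .mitochondria import DEFAULT_CAPACITY, step_pools_vectorized
from .network import (
    NODES,
    ConfigurationError,
    NetworkParameters,
    ScenarioConfig,
    apply_scenario,
)
from .population import Phenotype, classify_population, sample_agent_params

__all__ = ["PopulationTrajectory", "ReplicateSummary", "run_simulation", "run_replicates"]

#: population summaries are recorded every SUMMARY_EVERY days,
#: full per-cell state every CELL_EVERY days.
SUMMARY_EVERY = 0.1
CELL_EVERY = 1.0

_PHENOTYPE_COLUMNS = [p.name for p in Phenotype]


class _ParamStack:
    """Per-cell parameter arrays exposed through attribute access, so the
    scalar rate laws in :mod:`neurovuln.network` vectorize unchanged."""

    def __init__(self, params_list):
        import dataclasses as dc

        self._n = len(params_list)
        for f in dc.fields(NetworkParameters):
            setattr(
                self,
                f.name,
                np.array([getattr(p, f.name) for p in params_list], dtype=float),
            )


@dataclass
class PopulationTrajectory:
    """Recorded output of one simulation run.

    ``population_means`` averages over living cells only; ``phenotype_counts``
    rows always sum to the initial population size (DEAD included).
    ``per_cell`` is a long table thinned to one record per cell per
    :data:`CELL_EVERY` days.
    """

    time_grid: np.ndarray
    population_means: pd.DataFrame
    phenotype_counts: pd.DataFrame
    per_cell: pd.DataFrame
    deaths: pd.DataFrame
    config_echo: ScenarioConfig
    seed: int

    @property
    def n_cells(self) -> int:
        return int(self.config_echo.n_cells)


@dataclass
class ReplicateSummary:
    """Cross-replicate aggregate of matched simulation runs."""

    seeds: list
    mean_population_means: pd.DataFrame
    std_population_means: pd.DataFrame
    mean_phenotype_fractions: pd.DataFrame
    std_phenotype_fractions: pd.DataFrame
    mean_survival: pd.Series
    std_survival: pd.Series
    n_replicates: int
    trajectories: list = field(default_factory=list)


def _record_times(duration: float, dt: float, every: float) -> np.ndarray:
    stride = max(1, round(every / dt))
    n_steps = round(duration / dt)
    idx = np.arange(0, n_steps + 1, stride)
    if n_steps not in idx:
        idx = np.append(idx, n_steps)
    return idx


def run_simulation(config: ScenarioConfig, base: NetworkParameters | None = None) -> PopulationTrajectory:
    """Simulate one cell population under ``config``.

    Agents start resilient, at their own basal molecular fixed point, with
    fully healthy mitochondrial pools.  Fully reproducible from
    ``config.seed``.
    """
    config.validate()
    base = (base or NetworkParameters()).copy()
    base.validate()
    effective = apply_scenario(base, config)

    n = config.n_cells
    dt = config.dt
    n_steps = round(config.duration / dt)

    root = np.random.SeedSequence(config.seed)
    children = root.spawn(n + 1)
    cell_rngs = [np.random.default_rng(s) for s in children[:n]]
    event_rng = np.random.default_rng(children[n])

    cells = [
        sample_agent_params(effective, config.heterogeneity_cv, cell_rngs[i])
        for i in range(n)
    ]
    p = _ParamStack(cells)

    # basal molecular state per cell (age frozen at 0, intact pools)
    R, T, A = net._basal_arrays(p, n=n, tol=1e-9, max_steps=50_000)
    relax = net.relaxation_times(p, like=A)

    n_healthy = np.full(n, DEFAULT_CAPACITY, dtype=np.int64)
    n_damaged = np.zeros(n, dtype=np.int64)
    phen = np.zeros(n, dtype=np.int64)

    summary_steps = set(_record_times(config.duration, dt, SUMMARY_EVERY).tolist())
    cell_steps = set(_record_times(config.duration, dt, CELL_EVERY).tolist())

    sum_rows, phen_rows, cell_rows, death_rows = [], [], [], []
    times = []

    def fd_of():
        total = n_healthy + n_damaged
        return np.where(total > 0, n_damaged / np.maximum(total, 1), 1.0)

    def record(step):
        t = round(step * dt, 9)
        fd = fd_of()
        living = phen < Phenotype.DEAD
        if step in summary_steps:
            times.append(t)
            if living.any():
                means = [R[living].mean(), T[living].mean()] + [
                    A[living, j].mean() for j in range(len(NODES))
                ] + [fd[living].mean()]
            else:
                means = [np.nan] * (len(NODES) + 3)
            sum_rows.append(means + [int(living.sum())])
            phen_rows.append(np.bincount(phen, minlength=len(Phenotype)))
        if step in cell_steps:
            for i in np.nonzero(living)[0]:
                cell_rows.append(
                    (t, int(i), int(phen[i]), R[i], T[i])
                    + tuple(A[i])
                    + (int(n_healthy[i]), int(n_damaged[i]))
                )

    record(0)

    for step in range(1, n_steps + 1):
        t0 = (step - 1) * dt
        living = phen < Phenotype.DEAD
        fd = fd_of()

        # --- deterministic substep (RK4, fd frozen) -------------------
        k1 = net.state_rates(R, T, A, t0, fd, p, relax=relax)
        k2 = net.state_rates(
            R + 0.5 * dt * k1[0], T + 0.5 * dt * k1[1], A + 0.5 * dt * k1[2],
            t0 + 0.5 * dt, fd, p, relax=relax,
        )
        k3 = net.state_rates(
            R + 0.5 * dt * k2[0], T + 0.5 * dt * k2[1], A + 0.5 * dt * k2[2],
            t0 + 0.5 * dt, fd, p, relax=relax,
        )
        k4 = net.state_rates(
            R + dt * k3[0], T + dt * k3[1], A + dt * k3[2], t0 + dt, fd, p, relax=relax,
        )
        Rn = R + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        Tn = T + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        An = A + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        # dead cells are frozen
        R = np.where(living, np.maximum(Rn, 0.0), R)
        T = np.where(living, np.maximum(Tn, 0.0), T)
        A = np.where(living[:, None], np.clip(An, 0.0, 1.0), A)

        # --- stochastic substep ---------------------------------------
        t = round(step * dt, 9)
        bio = np.exp(-p.mito_biogenesis_decline * t)
        nh, nd = step_pools_vectorized(
            n_healthy, n_damaged, R, A[:, 8], A[:, 6], bio, dt, event_rng, p,
            uprmt=A[:, 0], tau=T,
        )
        n_healthy = np.where(living, nh, n_healthy)
        n_damaged = np.where(living, nd, n_damaged)

        phen = classify_population(
            A[:, 0], A[:, 1], R, T, p.vuln_ros_threshold, p.vuln_tau_threshold, phen
        )
        vulnerable = phen == Phenotype.VULNERABLE
        u = event_rng.random(n)
        dies = vulnerable & (u < -np.expm1(-p.death_hazard * dt))
        if dies.any():
            for i in np.nonzero(dies)[0]:
                death_rows.append((int(i), t))
            phen[dies] = Phenotype.DEAD

        record(step)

    times = np.asarray(times)
    mean_cols = ["ros", "tau", *NODES, "damaged_fraction", "n_living"]
    population_means = pd.DataFrame(sum_rows, index=times, columns=mean_cols)
    population_means.index.name = "time"
    phenotype_counts = pd.DataFrame(phen_rows, index=times, columns=_PHENOTYPE_COLUMNS)
    phenotype_counts.index.name = "time"
    per_cell = pd.DataFrame(
        cell_rows,
        columns=["time", "cell", "phenotype", "ros", "tau", *NODES, "n_healthy", "n_damaged"],
    )
    deaths = pd.DataFrame(death_rows, columns=["cell", "time"])

    return PopulationTrajectory(
        time_grid=times,
        population_means=population_means,
        phenotype_counts=phenotype_counts,
        per_cell=per_cell,
        deaths=deaths,
        config_echo=config,
        seed=config.seed,
    )


def run_replicates(
    config: ScenarioConfig,
    base: NetworkParameters | None = None,
    seeds: list[int] | None = None,
    *,
    keep_trajectories: bool = True,
) -> ReplicateSummary:
    """Run one simulation per seed and aggregate by time point."""
    import warnings

    if seeds is None:
        seeds = [config.seed + i for i in range(config.n_replicates)]
    if not seeds:
        raise ConfigurationError("seeds must be nonempty")
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds passed to run_replicates", stacklevel=2)

    import dataclasses as dc

    trajs = []
    for s in seeds:
        cfg = dc.replace(config, seed=int(s))
        trajs.append(run_simulation(cfg, base))

    means = [t.population_means[["ros", "tau", *NODES, "damaged_fraction"]] for t in trajs]
    fracs = [t.phenotype_counts / t.n_cells for t in trajs]
    survs = [100.0 * (1.0 - t.phenotype_counts["DEAD"] / t.n_cells) for t in trajs]

    mean_pm = sum(means) / len(means)
    std_pm = pd.concat(means).groupby(level=0).std(ddof=0)
    mean_fr = sum(fracs) / len(fracs)
    std_fr = pd.concat(fracs).groupby(level=0).std(ddof=0)
    surv_df = pd.concat(survs, axis=1)
    return ReplicateSummary(
        seeds=list(seeds),
        mean_population_means=mean_pm,
        std_population_means=std_pm,
        mean_phenotype_fractions=mean_fr,
        std_phenotype_fractions=std_fr,
        mean_survival=surv_df.mean(axis=1),
        std_survival=surv_df.std(axis=1, ddof=0),
        n_replicates=len(seeds),
        trajectories=trajs if keep_trajectories else [],
    )
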