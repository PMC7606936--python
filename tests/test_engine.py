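import dataclasses

import numpy as np
import pandas as pd
import pytest

from neurovuln import (
    NetworkParameters,
    Phenotype,
    ScenarioConfig,
    run_replicates,
    run_simulation,
    scenario_config,
)

from conftest import no_stress_params


def test_zero_duration_single_timepoint():
    cfg = ScenarioConfig(n_cells=20, duration=0.0, dt=0.01, seed=1)
    traj = run_simulation(cfg)
    assert len(traj.time_grid) == 1
    counts = traj.phenotype_counts.iloc[0]
    assert counts["RESILIENT"] == 20 and counts["DEAD"] == 0


def test_all_cells_start_resilient(small_normal_traj, small_tau_traj):
    for traj in (small_normal_traj, small_tau_traj):
        first = traj.phenotype_counts.iloc[0]
        assert first["RESILIENT"] == traj.n_cells


def test_bitwise_reproducibility():
    cfg = ScenarioConfig(n_cells=25, duration=3.0, dt=0.02, seed=77)
    a, b = run_simulation(cfg), run_simulation(cfg)
    pd.testing.assert_frame_equal(a.population_means, b.population_means)
    pd.testing.assert_frame_equal(a.per_cell, b.per_cell)
    pd.testing.assert_frame_equal(a.phenotype_counts, b.phenotype_counts)


def test_no_stress_world_is_quiescent():
    """With every stressor production silenced no phenotype transitions
    and no deaths occur over the full 20 days."""
    cfg = ScenarioConfig(n_cells=30, duration=20.0, dt=0.02, seed=5, heterogeneity_cv=0.0)
    traj = run_simulation(cfg, no_stress_params())
    assert (traj.phenotype_counts["RESILIENT"] == 30).all()
    assert traj.deaths.empty


def test_phenotype_counts_conserve_population(small_normal_traj, small_tau_traj):
    for traj in (small_normal_traj, small_tau_traj):
        assert (traj.phenotype_counts.sum(axis=1) == traj.n_cells).all()


def test_dead_count_is_nondecreasing(small_tau_traj):
    dead = small_tau_traj.phenotype_counts["DEAD"].values
    assert np.all(np.diff(dead) >= 0)


def test_phenotype_lattice_never_violated(small_tau_traj, small_normal_traj):
    """Per-cell recorded sequences respect the vulnerability lattice:
    VULNERABLE is absorbing among living records and no cell record ever
    reverts from it."""
    for traj in (small_tau_traj, small_normal_traj):
        for _, cell in traj.per_cell.groupby("cell"):
            ph = cell.sort_values("time").phenotype.values
            seen_vulnerable = False
            for state in ph:
                if seen_vulnerable:
                    assert state == int(Phenotype.VULNERABLE)
                seen_vulnerable = state == int(Phenotype.VULNERABLE)
        # dead cells never reappear in the living records
        for cell_id, t in traj.deaths.itertuples(index=False):
            later = traj.per_cell[(traj.per_cell.cell == cell_id) & (traj.per_cell.time > t)]
            assert later.empty


def test_activities_bounded_in_unit_interval(small_tau_traj):
    from neurovuln.network import NODES

    acts = small_tau_traj.per_cell[list(NODES)].values
    assert acts.min() >= 0.0 and acts.max() <= 1.0


def test_population_means_cover_living_cells_only(small_tau_traj):
    pm = small_tau_traj.population_means
    assert (pm.n_living == small_tau_traj.phenotype_counts.drop(columns="DEAD").sum(axis=1)).all()


def test_halving_dt_converged_at_default():
    """Population-mean ROS and activities at day 20 move < 1% when dt is
    halved (deterministic subsystem isolated)."""
    from neurovuln.network import NODES

    quiet = dataclasses.replace(
        NetworkParameters(), mito_damage_rate=0.0, mito_tau_damage_rate=0.0,
        death_hazard=0.0,
    )
    outs = []
    for dt in (0.02, 0.01):
        cfg = ScenarioConfig(n_cells=25, duration=20.0, dt=dt, seed=9)
        traj = run_simulation(cfg, quiet)
        outs.append(traj.population_means[["ros", *NODES]].iloc[-1])
    rel = np.abs(outs[0] - outs[1]) / np.maximum(np.abs(outs[1]), 1e-6)
    assert float(rel.max()) < 0.01


class TestReplicates:
    def test_single_seed_equals_its_run(self):
        cfg = ScenarioConfig(n_cells=20, duration=2.0, dt=0.02, seed=3)
        summary = run_replicates(cfg, seeds=[3])
        traj = run_simulation(cfg)
        pd.testing.assert_frame_equal(
            summary.mean_population_means,
            traj.population_means.drop(columns="n_living"),
        )
        assert (summary.std_survival == 0).all()

    def test_degenerate_replicates_have_zero_dispersion(self):
        cfg = ScenarioConfig(
            n_cells=15, duration=2.0, dt=0.02, seed=0, heterogeneity_cv=0.0
        )
        quiet = dataclasses.replace(
            NetworkParameters(), mito_damage_rate=0.0, mito_tau_damage_rate=0.0,
            death_hazard=0.0,
        )
        summary = run_replicates(cfg, quiet, seeds=[1, 2, 3])
        assert float(summary.std_population_means.max().max()) < 1e-12
        assert (summary.std_survival == 0).all()

    def test_duplicate_seeds_warn(self):
        cfg = ScenarioConfig(n_cells=5, duration=0.5, dt=0.05, seed=0)
        with pytest.warns(UserWarning):
            run_replicates(cfg, seeds=[1, 1])

    def test_replicate_error_shrinks_with_replicate_count(self):
        """SE of end-of-run survival decreases roughly like 1/sqrt(n)."""
        cfg = scenario_config("tau", n_cells=25, duration=14.0, dt=0.02)
        survs = []
        for s in range(16):
            t = run_simulation(dataclasses.replace(cfg, seed=100 + s))
            survs.append(100.0 * (1 - t.phenotype_counts["DEAD"].iloc[-1] / t.n_cells))
        survs = np.array(survs)
        se4 = survs[:4].std(ddof=1) / 2.0
        se16 = survs.std(ddof=1) / 4.0
        assert se16 < se4  # noisy, but the scaling direction must hold
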