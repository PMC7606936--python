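import numpy as np
import pandas as pd
import pytest

from neurovuln import (
    ScenarioConfig,
    correlation_r2,
    extrapolate_to_human_years,
    fold_change_signature,
    phenotype_fractions,
    survival_curve,
)
from neurovuln.engine import PopulationTrajectory
from neurovuln.network import NODES, InvalidParameterError
from neurovuln.outputs import correlation_by_group


def synthetic_trajectory(mean_rows, phen_rows=None, n_cells=10):
    """Hand-built trajectory for output-layer arithmetic tests (synthetic)."""
    times = np.array(sorted(mean_rows))
    pm = pd.DataFrame(
        [mean_rows[t] for t in times], index=times,
        columns=["ros", "tau", *NODES, "damaged_fraction", "n_living"],
    )
    pm.index.name = "time"
    if phen_rows is None:
        phen_rows = {t: [n_cells, 0, 0, 0, 0, 0] for t in times}
    pc = pd.DataFrame(
        [phen_rows[t] for t in times], index=times,
        columns=["RESILIENT", "MT_COMPROMISED", "ER_COMPROMISED",
                 "DUAL_COMPROMISED", "VULNERABLE", "DEAD"],
    )
    cfg = ScenarioConfig(n_cells=n_cells, duration=float(times[-1]), dt=0.01)
    return PopulationTrajectory(
        time_grid=times, population_means=pm, phenotype_counts=pc,
        per_cell=pd.DataFrame(), deaths=pd.DataFrame(columns=["cell", "time"]),
        config_echo=cfg, seed=0,
    )


def _row(act_value):
    return [0.1, 0.1] + [act_value] * len(NODES) + [0.0, 10]


class TestSignature:
    def test_reference_time_is_exactly_one(self, small_normal_traj):
        table = fold_change_signature(small_normal_traj)
        assert np.allclose(table.matrix[0.0].values, 1.0)
        assert (table.matrix.values > 0).all()

    def test_constant_trajectory_is_flat(self):
        traj = synthetic_trajectory({t: _row(0.4) for t in (0.0, 6.0, 11.0)})
        table = fold_change_signature(traj)
        assert np.allclose(table.matrix.values, 1.0)

    def test_midlife_fold_change_arithmetic(self):
        rows = {0.0: _row(0.30), 6.0: _row(0.60), 11.0: _row(0.45)}
        table = fold_change_signature(synthetic_trajectory(rows))
        assert np.allclose(table.mid_late["M"].values, 2.0)
        assert np.allclose(table.mid_late["L"].values, 1.5)

    def test_zero_reference_raises_naming_node(self):
        rows = {0.0: _row(0.3), 6.0: _row(0.5), 11.0: _row(0.5)}
        rows[0.0][2] = 0.0  # uprmt_hsp60 reference
        with pytest.raises(InvalidParameterError, match="uprmt_hsp60"):
            fold_change_signature(synthetic_trajectory(rows))

    def test_off_grid_reference_rejected(self, small_normal_traj):
        with pytest.raises(InvalidParameterError):
            fold_change_signature(small_normal_traj, t_ref=0.123456)

    def test_fold_changes_are_scale_free(self, small_normal_traj):
        """Scaling any node's trajectory by a positive constant leaves its
        fold-change row unchanged."""
        ref = fold_change_signature(small_normal_traj)
        scaled = small_normal_traj
        scaled.population_means["skn1"] *= 3.7
        try:
            out = fold_change_signature(scaled)
            pd.testing.assert_frame_equal(out.matrix, ref.matrix)
        finally:
            scaled.population_means["skn1"] /= 3.7


class TestPhenotypesAndSurvival:
    def test_startup_all_resilient(self, small_normal_traj):
        fr = phenotype_fractions(small_normal_traj)
        assert fr["RESILIENT"].iloc[0] == 1.0

    def test_fractions_sum_to_one(self, small_tau_traj):
        fr = phenotype_fractions(small_tau_traj)
        assert np.allclose(fr.sum(axis=1).values, 1.0, atol=1e-12)

    def test_survival_is_100_minus_dead_percentage(self, small_tau_traj):
        s = survival_curve(small_tau_traj)
        dead_pct = 100.0 * phenotype_fractions(small_tau_traj)["DEAD"]
        assert np.allclose(s.values, 100.0 - dead_pct.values)
        assert s.iloc[0] == 100.0
        assert np.all(np.diff(s.values) <= 0)

    def test_no_deaths_flat_survival(self, small_normal_traj):
        s = survival_curve(small_normal_traj)
        if small_normal_traj.deaths.empty:
            assert (s == 100.0).all()


class TestExtrapolation:
    @pytest.mark.parametrize("day,years", [(12.0, 60.0), (19.0, 95.0), (20.0, 100.0)])
    def test_nematode_day_to_human_years(self, day, years):
        assert extrapolate_to_human_years(day) == years

    def test_linearity(self):
        f = extrapolate_to_human_years
        assert f(7.0) + f(6.0) == pytest.approx(f(13.0))

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            extrapolate_to_human_years(-1.0)
        with pytest.raises(InvalidParameterError):
            extrapolate_to_human_years(5.0, lifespan_days=0.0)


class TestCorrelation:
    def test_perfect_agreement(self):
        x = pd.Series({"hsp-60": 1.2, "BiP": 0.8, "skn-1": 2.0, "mTOR": 0.5})
        assert correlation_r2(x, x) == pytest.approx(1.0)

    def test_constant_experimental_is_degenerate(self):
        sim = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        exp = pd.Series({"a": 1.5, "b": 1.5, "c": 1.5})
        assert np.isnan(correlation_r2(sim, exp))

    def test_identity_fit_matches_closed_form(self):
        """Four-pair toy table against the hand-computed 1 - SSres/SStot."""
        sim = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        exp = pd.Series({"a": 1.1, "b": 1.8, "c": 3.3, "d": 3.9})
        y = exp.values
        ss_res = np.sum((y - sim.values) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        expected = 1.0 - ss_res / ss_tot
        assert correlation_r2(sim, exp) == pytest.approx(expected, abs=1e-12)

    def test_ols_fit_is_squared_pearson(self):
        sim = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        exp = 2.0 * sim + 1.0  # offset line: identity fit penalized, OLS perfect
        assert correlation_r2(sim, exp, fit="ols") == pytest.approx(1.0)
        assert correlation_r2(sim, exp, fit="identity") < 1.0

    def test_too_few_pairs_rejected(self):
        sim = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(InvalidParameterError):
            correlation_r2(sim, sim)

    def test_grouped_experimental_table(self, small_normal_traj):
        table = fold_change_signature(small_normal_traj)
        exp = pd.DataFrame({
            "node": list(table.mid_late.index[:4]) * 2,
            "group": ["mid"] * 4 + ["late"] * 4,
            "fold_change": list(table.mid_late["M"].iloc[:4]) +
                           list(table.mid_late["L"].iloc[:4]),
        })
        out = correlation_by_group(table.mid_late, exp)
        assert out["mid"] == pytest.approx(1.0)
        assert out["late"] == pytest.approx(1.0)
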