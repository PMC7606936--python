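"""Derived analyses of simulation runs.

* the temporal molecular signature (per-node fold change vs the first day of
  adulthood, with mid-life and late-life summary columns),
* phenotype fractions and the survival curve,
* the linear nematode-day -> human-year extrapolation,
* coefficient-of-determination comparison of simulated against experimental
  fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import PopulationTrajectory
from .network import NODES, NODE_LABELS, InvalidParameterError
from .population import Phenotype

__all__ = [
    "SignatureTable",
    "fold_change_signature",
    "phenotype_fractions",
    "survival_curve",
    "extrapolate_to_human_years",
    "correlation_r2",
    "MIDLIFE_DAY",
    "LATELIFE_DAY",
]

#: sampling days for the mid-life (M) and late-life (L) signature columns
MIDLIFE_DAY = 6.0
LATELIFE_DAY = 11.0


@dataclass
class SignatureTable:
    """Node x time fold-change matrix normalized to a reference time.

    ``matrix`` rows are the nine signature nodes (conventional labels),
    columns are simulated days; every column-``t_ref`` entry equals 1.
    ``mid_late`` carries the mid-life (day 6) and late-life (day 11) summary columns.
    """

    matrix: pd.DataFrame
    mid_late: pd.DataFrame
    t_ref: float

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path, float_format="%.9g")


def fold_change_signature(traj: PopulationTrajectory, t_ref: float = 0.0) -> SignatureTable:
    """Population-mean activity of each node as fold change vs ``t_ref``.

    Raises if ``t_ref`` is off the recorded grid or any node's reference
    value is zero (fold change undefined for that node).
    """
    means = traj.population_means[list(NODES)]
    if t_ref not in means.index:
        raise InvalidParameterError(f"t_ref={t_ref} not on the recorded time grid")
    ref = means.loc[t_ref]
    zero = ref[ref == 0.0]
    if len(zero):
        raise InvalidParameterError(
            f"zero reference value at t={t_ref} for node(s): {list(zero.index)}"
        )
    fold = (means / ref).T
    fold.index = [NODE_LABELS[n] for n in fold.index]
    fold.index.name = "node"

    cols = {}
    for label, day in (("M", MIDLIFE_DAY), ("L", LATELIFE_DAY)):
        grid_day = means.index[np.argmin(np.abs(means.index.values - day))]
        cols[label] = fold[grid_day]
    mid_late = pd.DataFrame(cols)
    return SignatureTable(matrix=fold, mid_late=mid_late, t_ref=float(t_ref))


def phenotype_fractions(traj: PopulationTrajectory) -> pd.DataFrame:
    """Fraction of the initial population in each phenotype over time.

    Rows (states including DEAD) sum to 1 at every time point.
    """
    return traj.phenotype_counts / traj.n_cells


def survival_curve(traj: PopulationTrajectory) -> pd.Series:
    """Percent of the initial population still alive; starts at 100,
    nonincreasing."""
    dead = traj.phenotype_counts["DEAD"] / traj.n_cells
    s = 100.0 * (1.0 - dead)
    s.name = "percent_surviving"
    return s


def extrapolate_to_human_years(
    day: float, lifespan_days: float = 20.0, human_years: float = 100.0
) -> float:
    """Linear map from simulated nematode days to human years of age.

    With the default 20-day lifespan mapped onto 100 human years, day 12
    corresponds to 60 years and day 19 to 95 years.
    """
    if lifespan_days <= 0:
        raise InvalidParameterError("lifespan_days must be > 0")
    if np.any(np.asarray(day) < 0):
        raise InvalidParameterError("day must be >= 0")
    return day * human_years / lifespan_days


def correlation_r2(
    sim: pd.Series | dict,
    experimental: pd.Series | dict,
    *,
    fit: str = "identity",
) -> float:
    """Coefficient of determination of experimental vs simulated fold changes.

    ``fit="identity"`` (default) scores agreement against the 1:1 line:
    ``R^2 = 1 - sum((y - x)^2) / sum((y - mean(y))^2)`` with x the simulated
    and y the experimental fold changes — this matches plotting both against
    an ideal unit-slope trajectory and can be negative for poor agreement.
    ``fit="ols"`` instead reports the squared Pearson correlation (the R^2 of
    an ordinary least-squares line).

    Requires at least 3 matched keys; returns ``nan`` (degenerate) when the
    experimental values have zero variance.
    """
    sim = pd.Series(sim, dtype=float)
    exp = pd.Series(experimental, dtype=float)
    common = sim.index.intersection(exp.index)
    if len(common) < 3:
        raise InvalidParameterError(
            f"need >= 3 matched node keys, got {len(common)}"
        )
    x = sim.loc[common].values
    y = exp.loc[common].values
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    if fit == "identity":
        ss_res = float(np.sum((y - x) ** 2))
        return 1.0 - ss_res / ss_tot
    if fit == "ols":
        r = np.corrcoef(x, y)[0, 1]
        return float(r * r)
    raise InvalidParameterError(f"unknown fit convention {fit!r}")


def correlation_by_group(
    sim_table: pd.DataFrame,
    experimental: pd.DataFrame,
    *,
    fit: str = "identity",
) -> dict:
    """Per-group (mid/late) R^2 between a signature's M/L columns and a
    user-supplied experimental table with columns (node, group, fold_change).

    ``group`` values must be ``mid`` or ``late``; node names use the
    conventional labels (hsp-60, BiP, ...).
    """
    out = {}
    for group, col in (("mid", "M"), ("late", "L")):
        exp = experimental[experimental.group == group].set_index("node")["fold_change"]
        out[group] = correlation_r2(sim_table[col], exp, fit=fit)
    return out
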