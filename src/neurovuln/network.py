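"""Molecular stress-response network of the aging neuron.

The model tracks, per cell, a reactive-oxygen-species (ROS) pool, a tau
aggregate load, and nine normalized stress-response activities:

* ``uprmt_hsp60`` -- mitochondrial unfolded protein response (hsp-60 readout)
* ``uprer_bip``   -- total ER unfolded protein response (BiP readout)
* ``uprer_pperk`` -- translational branch of the UPR^ER (p-PERK readout)
* ``skn1``, ``daf16`` -- Nrf2/FoxO-ortholog oxidative stress regulators
* ``sod2``        -- mitochondrial superoxide dismutase activity
* ``bec1``        -- macroautophagy machinery
* ``mtor``        -- anti-autophagic activity
* ``pink1``       -- pro-mitophagy activity

Each activity is a saturable Hill-driven "response fraction" in [0, 1] that
relaxes toward a drive composed of activation/repression Hill terms on its
network inputs, multiplied by an exponentially age-declining capacity, by a
chronic-stress repression factor, and by a scenario expression scale.  The two
UPR hub nodes carry positive self-feedback (Hill coefficient >= 2), which --
together with chronic ROS/tau repression of their capacity -- makes their
steady-state response to sustained stress fold-bifurcate: a resilient high
branch and a compromised low branch (< 0.5) coexist over a stress window.

ROS production rises linearly with age and is amplified by damaged
mitochondria and tau load; clearance is boosted by sod-2/skn-1/daf-16.  Tau
production is boosted by ROS (a positive ROS<->tau loop) and cleared through
autophagy (bec-1) and the UPR^ER; the collapse of BiP activity therefore
accelerates tau accumulation, which is what makes the doubled-tau-aggregation
scenario qualitatively, not just quantitatively, more violent than normal
aging.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "NODES",
    "NODE_LABELS",
    "STATE_VARS",
    "InvalidParameterError",
    "ConfigurationError",
    "NodeActivities",
    "CellMolecularState",
    "NetworkParameters",
    "ScenarioConfig",
    "SCENARIOS",
    "scenario_config",
    "hill",
    "node_rates",
    "apply_scenario",
    "basal_state",
    "network_edges",
]

#: The nine dynamic signature nodes, in canonical order.
NODES = (
    "uprmt_hsp60",
    "uprer_bip",
    "uprer_pperk",
    "skn1",
    "daf16",
    "sod2",
    "bec1",
    "mtor",
    "pink1",
)

#: Field-name -> conventional gene/protein label used in tables and figures.
NODE_LABELS = {
    "uprmt_hsp60": "hsp-60",
    "uprer_bip": "BiP",
    "uprer_pperk": "p-PERK",
    "skn1": "skn-1",
    "daf16": "daf-16",
    "sod2": "sod-2",
    "bec1": "bec-1",
    "mtor": "mTOR",
    "pink1": "pink-1",
}

#: Full continuous state, in integration order.
STATE_VARS = ("ros", "tau") + NODES

# integer indices of the nodes inside an activity array
_I = {name: i for i, name in enumerate(NODES)}


class InvalidParameterError(ValueError):
    """A kinetic parameter violates its domain (e.g. K <= 0, n < 1)."""


class ConfigurationError(ValueError):
    """A scenario / run configuration is inconsistent or names unknown keys."""


# ---------------------------------------------------------------------------
# Hill kinetics
# ---------------------------------------------------------------------------

def hill(x, K, n, mode: str = "activation"):
    """Saturable Hill response.

    ``activation`` returns ``x**n / (K**n + x**n)``; ``repression`` returns
    ``K**n / (K**n + x**n)``.  Both lie in [0, 1] and sum to 1 at equal
    arguments.  ``x`` may be a scalar or array; ``K`` and ``n`` scalars or
    broadcastable arrays.
    """
    K = np.asarray(K, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(K <= 0.0):
        raise InvalidParameterError("Hill constant K must be strictly positive")
    if np.any(n < 1.0):
        raise InvalidParameterError("Hill coefficient n must be >= 1")
    if mode not in ("activation", "repression"):
        raise InvalidParameterError(f"unknown Hill mode {mode!r}")
    x = np.asarray(x, dtype=float)
    xn = np.power(x, n)
    Kn = np.power(K, n)
    out = xn / (Kn + xn) if mode == "activation" else Kn / (Kn + xn)
    if out.ndim == 0:
        return float(out)
    return out


def _act(x, K, n):
    # unchecked activation Hill for the hot integration path
    xn = x ** n
    return xn / (K ** n + xn)


def _rep(x, K, n):
    Kn = K ** n
    return Kn / (Kn + x ** n)


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------

@dataclass
class NodeActivities:
    """Normalized response fractions of the nine signature nodes."""

    uprmt_hsp60: float = 0.0
    uprer_bip: float = 0.0
    uprer_pperk: float = 0.0
    skn1: float = 0.0
    daf16: float = 0.0
    sod2: float = 0.0
    bec1: float = 0.0
    mtor: float = 0.0
    pink1: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in NODES], dtype=float)

    @classmethod
    def from_array(cls, a) -> "NodeActivities":
        a = np.asarray(a, dtype=float)
        if a.shape != (len(NODES),):
            raise ValueError(f"expected {len(NODES)} activities, got shape {a.shape}")
        return cls(**{name: float(a[i]) for i, name in enumerate(NODES)})

    def validate(self) -> None:
        for name in NODES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"activity {name}={v} outside [0, 1]")


@dataclass
class CellMolecularState:
    """One cell's continuous molecular state."""

    ros: float
    tau: float
    activities: NodeActivities
    age: float = 0.0

    def validate(self) -> None:
        if self.ros < 0 or self.tau < 0:
            raise InvalidParameterError("ros and tau must be non-negative")
        if self.age < 0:
            raise InvalidParameterError("age must be non-negative")
        self.activities.validate()

    def as_array(self) -> np.ndarray:
        return np.concatenate(([self.ros, self.tau], self.activities.as_array()))


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class NetworkParameters:
    """All rate constants of the molecular network (units: per simulated day).

    Defaults are the shipped calibration: they were fixed once, by
    ``scripts/calibrate.py``, against the population-level behavior of the
    normal-aging and tau-exacerbated scenarios (UPR threshold fractions at day
    20, ~5% cell loss at day 19 / day 14, vulnerability onset after day 12)
    and are frozen here and in ``data/default_params.yaml``.
    """

    # --- ROS pool -----------------------------------------------------
    ros_basal_production: float = 0.012     # basal production, 1/day
    ros_age_production: float = 0.194       # age-proportional production, 1/day^2
    ros_mito_coupling: float = 0.95         # amplification per damaged mito fraction
    ros_tau_coupling: float = 1.40          # max fold amplification by tau load
    ros_tau_saturation: float = 0.80        # tau load at half-maximal amplification
    ros_clearance_basal: float = 5.0       # first-order clearance, 1/day
    ros_clearance_weight_sod2: float = 0.20
    ros_clearance_weight_skn1: float = 0.16
    ros_clearance_weight_daf16: float = 0.16

    # --- tau aggregate load -------------------------------------------
    tau_production_basal: float = 0.09      # units/day
    tau_scenario_multiplier: float = 1.0    # 2.0 in the tau-exacerbated scenario
    tau_ros_boost: float = 1.4              # fold boost of production at saturating ROS
    tau_ros_K: float = 1.21
    tau_ros_n: float = 2.0
    tau_clearance_basal: float = 0.03       # 1/day
    tau_clearance_weight_bec1: float = 0.12
    tau_clearance_weight_uprer: float = 0.36

    # --- vulnerability / death ----------------------------------------
    vuln_ros_threshold: float = 1.66        # oxidative insult gate
    vuln_tau_threshold: float = 0.30        # proteotoxic insult gate
    death_hazard: float = 0.70              # 1/day while in the vulnerable state

    # --- mitochondrial pool -------------------------------------------
    mito_damage_rate: float = 0.35          # 1/day at saturating ROS
    mito_damage_K: float = 0.55
    mito_damage_n: float = 2.0
    mitophagy_rate: float = 2.0             # 1/day at full pink-1 x bec-1 activity
    mito_biogenesis_decline: float = 0.04   # 1/day decline of biogenesis capacity
    mito_tau_damage_rate: float = 0.60      # 1/day proteotoxic damage at saturating tau
    mito_tau_damage_K: float = 1.30
    mito_tau_damage_n: float = 2.0
    mito_uprmt_protection: float = 0.60     # hsp-60 shielding of proteotoxic damage

    # --- UPR^mt (hsp-60) ----------------------------------------------
    uprmt_basal_drive: float = 0.22
    uprmt_relaxation_time: float = 0.5
    uprmt_capacity_decline: float = 0.008
    uprmt_expression_scale: float = 1.0
    uprmt_ros_weight: float = 0.0           # direct ROS->UPRmt activation (off by default;
    uprmt_ros_K: float = 0.50               # activation is routed through mito damage)
    uprmt_ros_n: float = 2.0
    uprmt_mito_weight: float = 0.30
    uprmt_mito_K: float = 0.35
    uprmt_mito_n: float = 2.0
    uprmt_self_weight: float = 0.62
    uprmt_self_K: float = 0.45
    uprmt_self_n: float = 6.0
    uprmt_ros_stress_K: float = 2.22        # chronic-ROS capacity repression
    uprmt_ros_stress_n: float = 4.0
    uprmt_tau_stress_K: float = 4.20        # chronic tau-load capacity repression
    uprmt_tau_stress_n: float = 6.0
    uprmt_er_support_floor: float = 0.70    # residual capacity once UPR^ER has collapsed
    uprmt_er_support_K: float = 0.45        # BiP activity for half-maximal ER support
    uprmt_er_support_n: float = 4.0

    # --- UPR^ER, total (BiP) ------------------------------------------
    uprer_basal_drive: float = 0.53
    uprer_relaxation_time: float = 0.5
    uprer_capacity_decline: float = 0.006
    uprer_bip_expression_scale: float = 1.0
    uprer_ros_weight: float = 0.0
    uprer_ros_K: float = 0.50
    uprer_ros_n: float = 2.0
    uprer_tau_weight: float = 0.10          # acute tau -> UPR^ER activation
    uprer_tau_K: float = 0.50
    uprer_tau_n: float = 2.0
    uprer_self_weight: float = 0.35
    uprer_self_K: float = 0.40
    uprer_self_n: float = 4.0
    uprer_ros_stress_K: float = 3.45
    uprer_ros_stress_n: float = 4.0
    uprer_tau_stress_K: float = 0.95        # chronic tau-load capacity repression
    uprer_tau_stress_n: float = 6.0
    uprer_flux_stress_K: float = 2.24       # chronic aggregation-flux repression
    uprer_flux_stress_n: float = 6.0        # (K on the fold-increase-over-basal scale)

    # --- p-PERK (translational UPR^ER branch) -------------------------
    pperk_basal_drive: float = 0.15
    pperk_relaxation_time: float = 2.0      # deliberately slower than BiP
    pperk_capacity_decline: float = 0.004
    uprer_pperk_expression_scale: float = 1.0
    pperk_ros_weight: float = 0.20
    pperk_tau_weight: float = 0.45

    # --- skn-1 / daf-16 oxidative stress regulators -------------------
    skn1_basal_drive: float = 0.18
    skn1_relaxation_time: float = 0.5
    skn1_capacity_decline: float = 0.010
    skn1_expression_scale: float = 1.0
    skn1_ros_weight: float = 0.55
    skn1_ros_K: float = 0.56
    skn1_ros_n: float = 2.0

    daf16_basal_drive: float = 0.15
    daf16_relaxation_time: float = 0.5
    daf16_capacity_decline: float = 0.008
    daf16_expression_scale: float = 1.0
    daf16_ros_weight: float = 0.60
    daf16_ros_K: float = 0.63
    daf16_ros_n: float = 2.0

    # --- sod-2 --------------------------------------------------------
    sod2_basal_drive: float = 0.20
    sod2_relaxation_time: float = 0.8
    sod2_capacity_decline: float = 0.015
    sod2_expression_scale: float = 1.0
    sod2_skn1_weight: float = 0.45
    sod2_skn1_K: float = 0.40
    sod2_skn1_n: float = 2.0
    sod2_daf16_weight: float = 0.35
    sod2_daf16_K: float = 0.40
    sod2_daf16_n: float = 2.0

    # --- bec-1 (macroautophagy) ---------------------------------------
    bec1_basal_drive: float = 0.15
    bec1_relaxation_time: float = 0.8
    bec1_capacity_decline: float = 0.020
    bec1_expression_scale: float = 1.0
    bec1_skn1_weight: float = 0.30
    bec1_skn1_K: float = 0.40
    bec1_skn1_n: float = 2.0
    bec1_daf16_weight: float = 0.25
    bec1_daf16_K: float = 0.40
    bec1_daf16_n: float = 2.0
    bec1_mtor_weight: float = 0.30          # mTOR represses autophagy
    bec1_mtor_K: float = 0.50
    bec1_mtor_n: float = 2.0

    # --- mTOR ---------------------------------------------------------
    mtor_basal_drive: float = 0.75
    mtor_relaxation_time: float = 1.0
    mtor_capacity_decline: float = 0.050
    mtor_expression_scale: float = 1.0

    # --- pink-1 (mitophagy) -------------------------------------------
    pink1_basal_drive: float = 0.20
    pink1_relaxation_time: float = 0.8
    pink1_capacity_decline: float = 0.020
    pink1_expression_scale: float = 1.0
    pink1_skn1_weight: float = 0.30
    pink1_skn1_K: float = 0.40
    pink1_skn1_n: float = 2.0
    pink1_daf16_weight: float = 0.30
    pink1_daf16_K: float = 0.40
    pink1_daf16_n: float = 2.0

    # ------------------------------------------------------------------

    def copy(self) -> "NetworkParameters":
        return dataclasses.replace(self)

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in _SCALE_FIELDS:
                if v < 0:
                    raise InvalidParameterError(f"{f.name} must be >= 0, got {v}")
            elif f.name.endswith("_n"):
                if v < 1.0:
                    raise InvalidParameterError(f"{f.name} must be >= 1, got {v}")
            elif f.name.endswith(("_K", "_relaxation_time")):
                if v <= 0:
                    raise InvalidParameterError(f"{f.name} must be > 0, got {v}")
            else:
                if v < 0:
                    raise InvalidParameterError(f"{f.name} must be >= 0, got {v}")
        # bistability requirement on the UPR hub self-feedback
        if self.uprmt_self_n < 2 or self.uprer_self_n < 2:
            raise InvalidParameterError(
                "self-feedback Hill coefficients of uprmt_hsp60 and uprer_bip must be >= 2"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter(s): {sorted(unknown)}")
        p = cls(**{k: float(v) for k, v in d.items()})
        p.validate()
        return p


# scenario expression-scale fields (note the ER nodes' irregular names)
_SCALE_FIELDS = frozenset(
    f.name
    for f in dataclasses.fields(NetworkParameters)
    if f.name.endswith("_expression_scale")
)

#: Parameter fields that are structural: excluded from per-cell heterogeneity
#: sampling (Hill coefficients, topology/scenario knobs).
STRUCTURAL_FIELDS = frozenset(
    {f.name for f in dataclasses.fields(NetworkParameters) if f.name.endswith("_n")}
    | _SCALE_FIELDS
    | {"tau_scenario_multiplier"}
)


def scan_parameters(params: NetworkParameters | None = None) -> list[str]:
    """Names of the static scalar parameters included in sensitivity scans.

    Scenario knobs (expression scales, the tau scenario multiplier) are run
    conditions rather than kinetic constants and are excluded.
    """
    return [
        f.name
        for f in dataclasses.fields(NetworkParameters)
        if f.name not in _SCALE_FIELDS and f.name != "tau_scenario_multiplier"
    ]


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------

def activity_targets(R, T, A, age, fd, p):
    """Relaxation targets of the nine activities (vectorized).

    ``A`` has shape (..., 9) in :data:`NODES` order; ``R``, ``T``, ``age`` and
    ``fd`` (damaged mitochondrial fraction) broadcast against its leading
    dimensions.  ``p`` provides parameter attributes as scalars or arrays.

    Each target is ``min(drive, 1) * chronic_stress * exp(-lambda * age) *
    expression_scale`` clipped to [0, 1], so integrated activities can never
    leave the unit interval.
    """
    A = np.asarray(A, dtype=float)
    a_uprmt = A[..., 0]
    a_bip = A[..., 1]
    a_skn1 = A[..., 3]
    a_daf16 = A[..., 4]
    a_mtor = A[..., 7]

    tgt = np.empty_like(A)

    # UPR^mt: mito-damage activation + positive self-feedback, chronically
    # repressed by sustained ROS and tau load.  A collapsed UPR^ER drags
    # UPR^mt capacity down (ER dysregulation begets mitochondrial deficits):
    # full capacity requires BiP activity, with a floor once BiP is lost.
    drive = (
        p.uprmt_basal_drive
        + p.uprmt_ros_weight * _act(R, p.uprmt_ros_K, p.uprmt_ros_n)
        + p.uprmt_mito_weight * _act(fd, p.uprmt_mito_K, p.uprmt_mito_n)
        + p.uprmt_self_weight * _act(a_uprmt, p.uprmt_self_K, p.uprmt_self_n)
    )
    er_support = p.uprmt_er_support_floor + (1.0 - p.uprmt_er_support_floor) * _act(
        a_bip, p.uprmt_er_support_K, p.uprmt_er_support_n
    )
    stress = (
        _rep(R, p.uprmt_ros_stress_K, p.uprmt_ros_stress_n)
        * _rep(T, p.uprmt_tau_stress_K, p.uprmt_tau_stress_n)
        * er_support
    )
    tgt[..., 0] = (
        np.minimum(drive, 1.0)
        * stress
        * np.exp(-p.uprmt_capacity_decline * age)
        * p.uprmt_expression_scale
    )

    # UPR^ER total (BiP): acute tau activation + self-feedback, chronically
    # repressed by ROS and by the tau aggregation flux.  The flux input is the
    # fold-increase of aggregation over the basal (day-0, unstressed) rate, so
    # the ER folding burden tracks how hard misfolded protein is being
    # produced relative to the chaperone capacity the cell was built with.
    drive = (
        p.uprer_basal_drive
        + p.uprer_ros_weight * _act(R, p.uprer_ros_K, p.uprer_ros_n)
        + p.uprer_tau_weight * _act(T, p.uprer_tau_K, p.uprer_tau_n)
        + p.uprer_self_weight * _act(a_bip, p.uprer_self_K, p.uprer_self_n)
    )
    agg_flux_fold = p.tau_scenario_multiplier * (
        1.0 + p.tau_ros_boost * _act(R, p.tau_ros_K, p.tau_ros_n)
    )
    stress = (
        _rep(R, p.uprer_ros_stress_K, p.uprer_ros_stress_n)
        * _rep(T, p.uprer_tau_stress_K, p.uprer_tau_stress_n)
        * _rep(agg_flux_fold, p.uprer_flux_stress_K, p.uprer_flux_stress_n)
    )
    tgt[..., 1] = (
        np.minimum(drive, 1.0)
        * stress
        * np.exp(-p.uprer_capacity_decline * age)
        * p.uprer_bip_expression_scale
    )

    # p-PERK: same ER-stress inputs as BiP, slower, no chronic collapse --
    # the translational branch stays elevated under proteotoxic stress.
    drive = (
        p.pperk_basal_drive
        + p.pperk_ros_weight * _act(R, p.uprer_ros_K, p.uprer_ros_n)
        + p.pperk_tau_weight * _act(T, p.uprer_tau_K, p.uprer_tau_n)
    )
    tgt[..., 2] = (
        np.minimum(drive, 1.0)
        * np.exp(-p.pperk_capacity_decline * age)
        * p.uprer_pperk_expression_scale
    )

    # skn-1 / daf-16: ROS-activated transcription regulators.
    drive = p.skn1_basal_drive + p.skn1_ros_weight * _act(R, p.skn1_ros_K, p.skn1_ros_n)
    tgt[..., 3] = (
        np.minimum(drive, 1.0)
        * np.exp(-p.skn1_capacity_decline * age)
        * p.skn1_expression_scale
    )
    drive = p.daf16_basal_drive + p.daf16_ros_weight * _act(R, p.daf16_ros_K, p.daf16_ros_n)
    tgt[..., 4] = (
        np.minimum(drive, 1.0)
        * np.exp(-p.daf16_capacity_decline * age)
        * p.daf16_expression_scale
    )

    # sod-2: driven by skn-1 and daf-16.
    drive = (
        p.sod2_basal_drive
        + p.sod2_skn1_weight * _act(a_skn1, p.sod2_skn1_K, p.sod2_skn1_n)
        + p.sod2_daf16_weight * _act(a_daf16, p.sod2_daf16_K, p.sod2_daf16_n)
    )
    tgt[..., 5] = (
        np.minimum(drive, 1.0)
        * np.exp(-p.sod2_capacity_decline * age)
        * p.sod2_expression_scale
    )

    # bec-1: skn-1/daf-16 activation, mTOR repression.
    drive = (
        p.bec1_basal_drive
        + p.bec1_skn1_weight * _act(a_skn1, p.bec1_skn1_K, p.bec1_skn1_n)
        + p.bec1_daf16_weight * _act(a_daf16, p.bec1_daf16_K, p.bec1_daf16_n)
        + p.bec1_mtor_weight * _rep(a_mtor, p.bec1_mtor_K, p.bec1_mtor_n)
    )
    tgt[..., 6] = (
        np.minimum(drive, 1.0)
        * np.exp(-p.bec1_capacity_decline * age)
        * p.bec1_expression_scale
    )

    # mTOR: basal drive with pronounced age decline.
    tgt[..., 7] = (
        np.minimum(p.mtor_basal_drive, 1.0)
        * np.exp(-p.mtor_capacity_decline * age)
        * p.mtor_expression_scale
        * np.ones_like(a_mtor)
    )

    # pink-1: skn-1/daf-16-driven mitophagy.
    drive = (
        p.pink1_basal_drive
        + p.pink1_skn1_weight * _act(a_skn1, p.pink1_skn1_K, p.pink1_skn1_n)
        + p.pink1_daf16_weight * _act(a_daf16, p.pink1_daf16_K, p.pink1_daf16_n)
    )
    tgt[..., 8] = (
        np.minimum(drive, 1.0)
        * np.exp(-p.pink1_capacity_decline * age)
        * p.pink1_expression_scale
    )

    np.clip(tgt, 0.0, 1.0, out=tgt)
    return tgt


def relaxation_times(p, like=None) -> np.ndarray:
    """Per-node relaxation times as a (..., 9) array broadcast like ``like``."""
    taus = [
        p.uprmt_relaxation_time,
        p.uprer_relaxation_time,
        p.pperk_relaxation_time,
        p.skn1_relaxation_time,
        p.daf16_relaxation_time,
        p.sod2_relaxation_time,
        p.bec1_relaxation_time,
        p.mtor_relaxation_time,
        p.pink1_relaxation_time,
    ]
    out = np.stack(np.broadcast_arrays(*[np.asarray(t, dtype=float) for t in taus]), axis=-1)
    if like is not None:
        out = np.broadcast_to(out, np.shape(like)).copy()
    return out


def state_rates(R, T, A, age, fd, p, relax=None):
    """Right-hand side of the continuous subsystem (vectorized).

    Returns ``(dR, dT, dA)`` where ``dA`` has shape (..., 9).  ``relax`` may
    pass precomputed relaxation times to avoid re-stacking in inner loops.
    """
    A = np.asarray(A, dtype=float)
    tgt = activity_targets(R, T, A, age, fd, p)
    if relax is None:
        relax = relaxation_times(p, like=A)
    dA = (tgt - A) / relax

    a_bip = A[..., 1]
    a_skn1 = A[..., 3]
    a_daf16 = A[..., 4]
    a_sod2 = A[..., 5]
    a_bec1 = A[..., 6]

    production = (p.ros_basal_production + p.ros_age_production * age) * (
        1.0
        + p.ros_mito_coupling * fd
        + p.ros_tau_coupling * T / (T + p.ros_tau_saturation)
    )
    clearance = (
        p.ros_clearance_basal
        + p.ros_clearance_weight_sod2 * a_sod2
        + p.ros_clearance_weight_skn1 * a_skn1
        + p.ros_clearance_weight_daf16 * a_daf16
    )
    dR = production - R * clearance

    tau_prod = (
        p.tau_production_basal
        * p.tau_scenario_multiplier
        * (1.0 + p.tau_ros_boost * _act(R, p.tau_ros_K, p.tau_ros_n))
    )
    tau_clear = (
        p.tau_clearance_basal
        + p.tau_clearance_weight_bec1 * a_bec1
        + p.tau_clearance_weight_uprer * a_bip
    )
    dT = tau_prod - T * tau_clear

    return dR, dT, dA


def node_rates(
    state: CellMolecularState,
    params: NetworkParameters,
    damaged_fraction: float,
) -> np.ndarray:
    """Full right-hand side for one cell, in :data:`STATE_VARS` order.

    Deterministic: identical inputs give bitwise-identical outputs.
    """
    state.validate()
    params.validate()
    A = state.activities.as_array()
    dR, dT, dA = state_rates(
        float(state.ros), float(state.tau), A, float(state.age), float(damaged_fraction), params
    )
    return np.concatenate(([dR, dT], dA))


def basal_state(
    params: NetworkParameters,
    *,
    tol: float = 1e-10,
    max_steps: int = 200_000,
    dt: float = 0.02,
) -> CellMolecularState:
    """Unstressed (age-frozen, undamaged) fixed point of one cell's network.

    Integrates the rate laws with age clamped at 0 and an intact mitochondrial
    pool from a high-activity start, so that the bistable UPR hubs settle on
    their resilient branch.  This is the state every agent is initialized to.
    """
    R, T, A = _basal_arrays(params, tol=tol, max_steps=max_steps, dt=dt)
    return CellMolecularState(
        ros=float(R), tau=float(T), activities=NodeActivities.from_array(A), age=0.0
    )


def _basal_arrays(p, *, tol=1e-10, max_steps=200_000, dt=0.02, n=None):
    """Vectorized basal fixed-point solve; ``n`` cells if params are stacked."""
    shape = () if n is None else (n,)
    R = np.zeros(shape) + 0.05
    T = np.zeros(shape) + 0.05
    A = np.full(shape + (len(NODES),), 0.9)
    relax = relaxation_times(p, like=A)
    for _ in range(max_steps):
        dR, dT, dA = state_rates(R, T, A, 0.0, 0.0, p, relax=relax)
        R = np.maximum(R + dt * dR, 0.0)
        T = np.maximum(T + dt * dT, 0.0)
        A = np.clip(A + dt * dA, 0.0, 1.0)
        m = max(
            np.max(np.abs(dR)) if np.size(dR) else 0.0,
            np.max(np.abs(dT)),
            np.max(np.abs(dA)),
        )
        if m < tol:
            break
    return R, T, A


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """One simulation run condition.

    ``tau_multiplier`` scales the tau aggregation rate (2.0 models a 100%
    increase); ``node_scales`` multiplies per-node expression (0.10 models a
    90% knockdown, 1.50 a 50% overexpression).
    """

    scenario_name: str = "normal"
    tau_multiplier: float = 1.0
    node_scales: dict = field(default_factory=dict)
    n_cells: int = 500
    duration: float = 20.0
    dt: float = 0.005
    seed: int = 0
    n_replicates: int = 10
    heterogeneity_cv: float = 0.10

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if self.duration < 0:
            raise ConfigurationError("duration must be >= 0")
        if not (0 < self.dt <= 0.1):
            raise ConfigurationError("dt must satisfy 0 < dt <= 0.1 day")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.heterogeneity_cv < 0:
            raise ConfigurationError("heterogeneity_cv must be >= 0")
        if self.tau_multiplier < 0:
            raise ConfigurationError("tau_multiplier must be >= 0")
        for node in self.node_scales:
            if node not in NODES:
                raise ConfigurationError(
                    f"unknown node {node!r} in node_scales; expected one of {NODES}"
                )


#: Named scenario presets: (tau multiplier, node expression scales).
SCENARIOS: dict[str, tuple[float, dict]] = {
    "normal": (1.0, {}),
    "tau": (2.0, {}),
    "skn1-ablation": (1.0, {"skn1": 0.10}),
    "skn1-oe": (1.0, {"skn1": 1.50}),
    "daf16-deficient": (1.0, {"daf16": 0.10}),
    "uprmt-deficient": (1.0, {"uprmt_hsp60": 0.10}),
    "uprer-deficient": (1.0, {"uprer_bip": 0.10, "uprer_pperk": 0.10}),
    "tau-skn1-ablation": (2.0, {"skn1": 0.10}),
    "tau-skn1-oe": (2.0, {"skn1": 1.50}),
    "tau-daf16-deficient": (2.0, {"daf16": 0.10}),
    "tau-uprmt-deficient": (2.0, {"uprmt_hsp60": 0.10}),
    "tau-uprer-deficient": (2.0, {"uprer_bip": 0.10, "uprer_pperk": 0.10}),
}
SCENARIOS["skn1-deficient"] = SCENARIOS["skn1-ablation"]
SCENARIOS["tau-skn1-deficient"] = SCENARIOS["tau-skn1-ablation"]


def scenario_config(name: str, **overrides) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a named preset."""
    if name not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}"
        )
    tau_mult, scales = SCENARIOS[name]
    cfg = ScenarioConfig(
        scenario_name=name, tau_multiplier=tau_mult, node_scales=dict(scales), **overrides
    )
    cfg.validate()
    return cfg


# scale field names are irregular for the two ER nodes
_SCALE_FIELD_BY_NODE = {
    "uprmt_hsp60": "uprmt_expression_scale",
    "uprer_bip": "uprer_bip_expression_scale",
    "uprer_pperk": "uprer_pperk_expression_scale",
    "skn1": "skn1_expression_scale",
    "daf16": "daf16_expression_scale",
    "sod2": "sod2_expression_scale",
    "bec1": "bec1_expression_scale",
    "mtor": "mtor_expression_scale",
    "pink1": "pink1_expression_scale",
}


def apply_scenario(base: NetworkParameters, scenario: ScenarioConfig) -> NetworkParameters:
    """Return a copy of ``base`` with the scenario perturbations applied.

    Sets the tau scenario multiplier and multiplies each named node's
    expression scale; ``base`` is left unmodified.
    """
    base.validate()
    scenario.validate()
    changes = {"tau_scenario_multiplier": scenario.tau_multiplier}
    for node, scale in scenario.node_scales.items():
        if node not in _SCALE_FIELD_BY_NODE:
            raise ConfigurationError(f"unknown node {node!r} in node_scales")
        fname = _SCALE_FIELD_BY_NODE[node]
        changes[fname] = getattr(base, fname) * float(scale)
    return dataclasses.replace(base, **changes)


# ---------------------------------------------------------------------------
# Topology export
# ---------------------------------------------------------------------------

def network_edges(params: NetworkParameters | None = None) -> list[dict]:
    """Edge list (source, target, sign, K, n) of the regulatory topology."""
    p = params or NetworkParameters()
    edges = [
        ("ros", "skn1", "+", p.skn1_ros_K, p.skn1_ros_n),
        ("ros", "daf16", "+", p.daf16_ros_K, p.daf16_ros_n),
        ("ros", "tau", "+", p.tau_ros_K, p.tau_ros_n),
        ("ros", "uprmt_hsp60", "-", p.uprmt_ros_stress_K, p.uprmt_ros_stress_n),
        ("ros", "uprer_bip", "-", p.uprer_ros_stress_K, p.uprer_ros_stress_n),
        ("ros", "uprer_pperk", "+", p.uprer_ros_K, p.uprer_ros_n),
        ("ros", "mitochondria", "+", p.mito_damage_K, p.mito_damage_n),
        ("tau", "ros", "+", float("nan"), float("nan")),
        ("tau", "uprer_bip", "+", p.uprer_tau_K, p.uprer_tau_n),
        ("tau", "uprer_pperk", "+", p.uprer_tau_K, p.uprer_tau_n),
        ("tau", "uprer_bip", "-", p.uprer_flux_stress_K, p.uprer_flux_stress_n),
        ("tau", "uprmt_hsp60", "-", p.uprmt_tau_stress_K, p.uprmt_tau_stress_n),
        ("mito_damage", "uprmt_hsp60", "+", p.uprmt_mito_K, p.uprmt_mito_n),
        ("mito_damage", "ros", "+", float("nan"), float("nan")),
        ("uprmt_hsp60", "uprmt_hsp60", "+", p.uprmt_self_K, p.uprmt_self_n),
        ("uprer_bip", "uprer_bip", "+", p.uprer_self_K, p.uprer_self_n),
        ("uprer_bip", "tau", "-", float("nan"), float("nan")),
        ("skn1", "sod2", "+", p.sod2_skn1_K, p.sod2_skn1_n),
        ("daf16", "sod2", "+", p.sod2_daf16_K, p.sod2_daf16_n),
        ("skn1", "bec1", "+", p.bec1_skn1_K, p.bec1_skn1_n),
        ("daf16", "bec1", "+", p.bec1_daf16_K, p.bec1_daf16_n),
        ("mtor", "bec1", "-", p.bec1_mtor_K, p.bec1_mtor_n),
        ("skn1", "pink1", "+", p.pink1_skn1_K, p.pink1_skn1_n),
        ("daf16", "pink1", "+", p.pink1_daf16_K, p.pink1_daf16_n),
        ("skn1", "ros", "-", float("nan"), float("nan")),
        ("daf16", "ros", "-", float("nan"), float("nan")),
        ("sod2", "ros", "-", float("nan"), float("nan")),
        ("bec1", "tau", "-", float("nan"), float("nan")),
    ]
    return [
        {"source": s, "target": t, "sign": sign, "K": K, "n": n}
        for s, t, sign, K, n in edges
    ]
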