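"""Cell agents: sampled heterogeneity, the vulnerability state machine, death.

Phenotypes form a lattice of increasing vulnerability::

    RESILIENT -> {MT_COMPROMISED, ER_COMPROMISED} -> DUAL_COMPROMISED
              -> VULNERABLE -> DEAD

A cell is mitochondria-compromised while its UPR^mt activity is below 0.50
and ER-compromised while its UPR^ER (BiP) activity is below 0.50.  The
compromised flags are re-evaluated every step (the dynamics' hysteresis makes
reversal rare without hard-coding it), but VULNERABLE -- reached when both
flags hold and the oxidative and proteotoxic loads exceed their thresholds --
and DEAD are absorbing.  Vulnerable cells die with a constant hazard.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .mitochondria import MitoPool
from .network import (
    STRUCTURAL_FIELDS,
    CellMolecularState,
    NetworkParameters,
)

__all__ = [
    "Phenotype",
    "CellAgent",
    "sample_agent_params",
    "classify_phenotype",
    "death_event",
]


class Phenotype(enum.IntEnum):
    """Cellular vulnerability states, ordered by severity."""

    RESILIENT = 0
    MT_COMPROMISED = 1
    ER_COMPROMISED = 2
    DUAL_COMPROMISED = 3
    VULNERABLE = 4
    DEAD = 5


#: Activity level below which a stress response counts as compromised.
COMPROMISED_THRESHOLD = 0.50


@dataclass
class CellAgent:
    """One cell: its sampled parameters, molecular state, organelles, fate."""

    id: int
    params: NetworkParameters
    molecular: CellMolecularState
    mito: MitoPool
    phenotype: Phenotype = Phenotype.RESILIENT


def sample_agent_params(
    base: NetworkParameters,
    cv: float,
    rng: np.random.Generator,
) -> NetworkParameters:
    """Draw one cell's parameters around ``base``.

    Every non-structural positive parameter is multiplied by an independent
    Gaussian factor (mean 1, sd ``cv``) truncated to ``[1 - 3 cv, 1 + 3 cv]``
    and floored at a small positive value.  Hill coefficients, expression
    scales and the tau scenario multiplier are structural and left unchanged.
    ``cv = 0`` returns an exact copy.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv >= 1.0 / 3.0:
        warnings.warn(
            "heterogeneity cv >= 1/3: the +-3 cv truncation materially distorts "
            "the sampling distribution",
            stacklevel=2,
        )
    if cv == 0:
        return base.copy()

    changes = {}
    for f in dataclasses.fields(base):
        if f.name in STRUCTURAL_FIELDS:
            continue
        value = getattr(base, f.name)
        factor = float(np.clip(rng.normal(1.0, cv), 1.0 - 3.0 * cv, 1.0 + 3.0 * cv))
        changes[f.name] = max(value * factor, 1e-12)
    return dataclasses.replace(base, **changes)


def classify_phenotype(
    uprmt: float,
    uprer: float,
    ros: float,
    tau: float,
    thresholds: tuple[float, float],
    current: Phenotype,
) -> Phenotype:
    """Re-evaluate one cell's phenotype from its molecular readouts.

    ``thresholds`` is ``(ros_threshold, tau_threshold)``.  VULNERABLE and
    DEAD are sticky; the compromised flags are otherwise recomputed from the
    instantaneous UPR activities.
    """
    if current in (Phenotype.VULNERABLE, Phenotype.DEAD):
        return current
    ros_thr, tau_thr = thresholds
    mt = uprmt < COMPROMISED_THRESHOLD
    er = uprer < COMPROMISED_THRESHOLD
    if mt and er:
        if ros > ros_thr and tau > tau_thr:
            return Phenotype.VULNERABLE
        return Phenotype.DUAL_COMPROMISED
    if mt:
        return Phenotype.MT_COMPROMISED
    if er:
        return Phenotype.ER_COMPROMISED
    return Phenotype.RESILIENT


def classify_population(
    uprmt: np.ndarray,
    uprer: np.ndarray,
    ros: np.ndarray,
    tau: np.ndarray,
    ros_thr: np.ndarray,
    tau_thr: np.ndarray,
    current: np.ndarray,
) -> np.ndarray:
    """Vectorized :func:`classify_phenotype` over integer phenotype codes."""
    mt = uprmt < COMPROMISED_THRESHOLD
    er = uprer < COMPROMISED_THRESHOLD
    new = np.zeros_like(current)
    new[mt & ~er] = Phenotype.MT_COMPROMISED
    new[er & ~mt] = Phenotype.ER_COMPROMISED
    dual = mt & er
    new[dual] = Phenotype.DUAL_COMPROMISED
    new[dual & (ros > ros_thr) & (tau > tau_thr)] = Phenotype.VULNERABLE
    sticky = current >= Phenotype.VULNERABLE
    new[sticky] = current[sticky]
    return new


def death_event(
    phenotype: Phenotype,
    hazard: float,
    dt: float,
    rng: np.random.Generator,
) -> bool:
    """Rate-dependent death: only VULNERABLE cells can die.

    Returns True with probability ``1 - exp(-hazard * dt)`` when the cell is
    vulnerable, False otherwise.
    """
    if hazard < 0:
        raise ValueError("hazard must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if phenotype is not Phenotype.VULNERABLE:
        return False
    return bool(rng.random() < -np.expm1(-hazard * dt))
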