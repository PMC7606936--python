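"""Per-cell mitochondrion agent pool.

Each cell carries a pool of up to ``capacity`` mitochondria, each either
healthy or damaged.  Per time step, healthy organelles are damaged with a
ROS-dependent hazard, damaged ones are removed by mitophagy (driven by the
pink-1 x bec-1 activity product), and removed slots are refilled by
biogenesis with an age-declining success probability.  Because the organelles
are exchangeable two-state agents, the per-organelle event process is sampled
exactly with batched binomial draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import hill

__all__ = ["MitoPool", "step_mitochondria", "damaged_fraction"]

logger = logging.getLogger(__name__)

#: Default number of mitochondrial slots per cell.
DEFAULT_CAPACITY = 100


@dataclass
class MitoPool:
    """Counts of healthy and damaged mitochondria in one cell."""

    n_healthy: int
    n_damaged: int = 0
    capacity: int = DEFAULT_CAPACITY

    def validate(self) -> None:
        if self.capacity <= 0:
            raise ValueError("capacity must be positive")
        if self.n_healthy < 0 or self.n_damaged < 0:
            raise ValueError("counts must be non-negative")
        if self.n_healthy + self.n_damaged > self.capacity:
            raise ValueError("pool exceeds capacity")


def damaged_fraction(pool: MitoPool) -> float:
    """Damaged fraction of the present organelles; an empty pool counts as
    fully failed (1.0)."""
    total = pool.n_healthy + pool.n_damaged
    if total == 0:
        logger.debug("empty mitochondrial pool treated as fully failed")
        return 1.0
    return pool.n_damaged / total


def step_mitochondria(
    pool: MitoPool,
    ros: float,
    pink1: float,
    bec1: float,
    biogenesis_capacity: float,
    dt: float,
    rng: np.random.Generator,
    *,
    damage_rate: float = 0.35,
    damage_K: float = 0.60,
    damage_n: float = 2.0,
    mitophagy_rate: float = 2.0,
    tau: float = 0.0,
    tau_damage_rate: float = 0.50,
    tau_damage_K: float = 1.30,
    tau_damage_n: float = 2.0,
    uprmt: float = 0.0,
    uprmt_protection: float = 0.0,
) -> MitoPool:
    """Advance one pool by ``dt`` days.

    Healthy organelles are damaged with a hazard composed of an oxidative
    term ``damage_rate * hill(ros)`` and a proteotoxic term
    ``tau_damage_rate * hill(tau)``; the mitochondrial unfolded protein
    response shields against the proteotoxic term only (factor
    ``1 - uprmt_protection * uprmt``).  Damaged organelles are cleared with
    probability ``1 - exp(-mitophagy_rate * pink1 * bec1 * dt)``; each
    cleared slot is refilled healthy with probability
    ``biogenesis_capacity``.  Counts are drawn binomially, so the update is
    exact for exchangeable organelles.  ``dt <= 0`` returns the pool
    unchanged.
    """
    pool.validate()
    if dt <= 0:
        return MitoPool(pool.n_healthy, pool.n_damaged, pool.capacity)

    shield = 1.0 - np.clip(uprmt_protection * uprmt, 0.0, 1.0)
    hazard = damage_rate * hill(ros, damage_K, damage_n) + (
        tau_damage_rate * shield * hill(tau, tau_damage_K, tau_damage_n) if tau > 0 else 0.0
    )
    p_dam = -np.expm1(-hazard * dt)
    p_clear = -np.expm1(-mitophagy_rate * pink1 * bec1 * dt)

    n_new_damage = int(rng.binomial(pool.n_healthy, p_dam))
    n_removed = int(rng.binomial(pool.n_damaged, p_clear))
    n_reborn = int(rng.binomial(n_removed, float(np.clip(biogenesis_capacity, 0.0, 1.0))))

    out = MitoPool(
        n_healthy=pool.n_healthy - n_new_damage + n_reborn,
        n_damaged=pool.n_damaged + n_new_damage - n_removed,
        capacity=pool.capacity,
    )
    out.validate()
    return out


def step_pools_vectorized(
    n_healthy: np.ndarray,
    n_damaged: np.ndarray,
    ros: np.ndarray,
    pink1: np.ndarray,
    bec1: np.ndarray,
    biogenesis_capacity: float | np.ndarray,
    dt: float,
    rng: np.random.Generator,
    p,
    uprmt: np.ndarray | float = 0.0,
    tau: np.ndarray | float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched pool update across a cell population (engine inner loop).

    Statistically identical to applying :func:`step_mitochondria` cell by
    cell; draws use one vectorized stream in fixed cell order.
    """
    from .network import _act  # unchecked Hill on the hot path

    shield = 1.0 - np.clip(p.mito_uprmt_protection * uprmt, 0.0, 1.0)
    hazard = p.mito_damage_rate * _act(ros, p.mito_damage_K, p.mito_damage_n) + (
        p.mito_tau_damage_rate
        * shield
        * _act(tau, p.mito_tau_damage_K, p.mito_tau_damage_n)
    )
    p_dam = -np.expm1(-hazard * dt)
    p_clear = -np.expm1(-p.mitophagy_rate * pink1 * bec1 * dt)
    bio = np.clip(np.broadcast_to(np.asarray(biogenesis_capacity, float), n_healthy.shape), 0.0, 1.0)

    new_damage = rng.binomial(n_healthy, p_dam)
    removed = rng.binomial(n_damaged, p_clear)
    reborn = rng.binomial(removed, bio)
    return n_healthy - new_damage + reborn, n_damaged + new_damage - removed
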