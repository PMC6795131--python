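"""Motor-unit pool construction and recruitment schedules.

Computational fibers are grouped into motor units (MUs) whose sizes follow an
exponential (geometric) progression, and MUs are recruited from smallest to
largest following Henneman's size principle.  The canonical ten-unit pool for
225 fibers has sizes {1, 2, 3, 5, 8, 14, 21, 33, 53, 85}: its six smallest
units hold 33 fibers, i.e. 14.67% of the pool, pinning the geometric ratio
(about 1.6).

Because all fibers behave identically in the quasi-1D reduction, fibers of
one MU share a single electrophysiology / cross-bridge solution; the
homogenized activation is the size-weighted average over recruited MUs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import PoolConfig

__all__ = [
    "MotorUnitPool",
    "CANONICAL_SIZES_225_10",
    "build_pool",
    "recruitment_schedule",
    "pool_activation",
]

#: Canonical fiber counts per MU for the 225-fiber / 10-MU pool (ascending).
CANONICAL_SIZES_225_10 = (1, 2, 3, 5, 8, 14, 21, 33, 53, 85)


@dataclass(frozen=True)
class MotorUnitPool:
    """Fibers per MU (ascending) and per-MU recruitment times."""

    sizes: tuple[int, ...]
    stim_times: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if list(self.sizes) != sorted(self.sizes):
            raise ValueError("MU sizes must be non-decreasing")
        if any(s < 1 for s in self.sizes):
            raise ValueError("every MU must hold at least one fiber")
        if self.stim_times and list(self.stim_times) != sorted(self.stim_times):
            raise ValueError("stim_times must be non-decreasing (Henneman order)")

    @property
    def n_mu(self) -> int:
        return len(self.sizes)

    @property
    def n_fibers(self) -> int:
        return sum(self.sizes)

    @property
    def weights(self) -> np.ndarray:
        """Fractional fiber weight of each MU (sums to 1)."""
        return np.asarray(self.sizes, dtype=float) / self.n_fibers


def _geometric_sizes(n_fibers: int, n_mu: int, ratio: float = 1.6) -> tuple[int, ...]:
    """Integer MU sizes from a geometric progression summing to n_fibers."""
    raw = np.array([ratio**i for i in range(n_mu)])
    raw *= n_fibers / raw.sum()
    sizes = np.maximum(1, np.round(raw).astype(int))
    # absorb the rounding remainder in the largest unit
    sizes[-1] += n_fibers - sizes.sum()
    sizes = np.sort(sizes)
    if sizes[0] < 1 or sizes.sum() != n_fibers:
        raise ValueError(
            f"cannot distribute {n_fibers} fibers over {n_mu} exponential MUs"
        )
    return tuple(int(s) for s in sizes)


def build_pool(pc: PoolConfig) -> MotorUnitPool:
    """Motor-unit pool for a pool configuration (no recruitment times yet)."""
    if (pc.n_fibers, pc.n_mu) == (225, 10):
        sizes = CANONICAL_SIZES_225_10
    elif pc.n_mu == 1:
        sizes = (pc.n_fibers,)
    else:
        sizes = _geometric_sizes(pc.n_fibers, pc.n_mu)
    assert sum(sizes) == pc.n_fibers
    pool = MotorUnitPool(sizes=sizes)
    return recruitment_schedule(pool, pc.recruited_mu, pc.inter_mu_delay)


def recruitment_schedule(
    pool: MotorUnitPool, recruited_mu: int, inter_mu_delay: float
) -> MotorUnitPool:
    """Henneman-ordered recruitment times: MU i fires at i * delay.

    Units beyond ``recruited_mu`` are never recruited (time = +inf); zero
    delay reproduces synchronous stimulation of the recruited subset.
    """
    if not 1 <= recruited_mu <= pool.n_mu:
        raise ValueError("recruited_mu must lie in [1, n_mu]")
    if inter_mu_delay < 0:
        raise ValueError("inter_mu_delay must be non-negative")
    times = tuple(
        i * inter_mu_delay if i < recruited_mu else math.inf
        for i in range(pool.n_mu)
    )
    return MotorUnitPool(sizes=pool.sizes, stim_times=times)


def pool_activation(mu_traces: dict[int, np.ndarray], pool: MotorUnitPool) -> np.ndarray:
    """Homogenized activation: size-weighted average of per-MU gamma traces.

    ``mu_traces`` maps MU index to an activation array (any common shape,
    e.g. time x element); every recruited MU must be present, unrecruited
    MUs contribute zero.
    """
    if not pool.stim_times:
        raise ValueError("pool has no recruitment schedule")
    recruited = [i for i, t in enumerate(pool.stim_times) if math.isfinite(t)]
    missing = [i for i in recruited if i not in mu_traces]
    if missing:
        raise ValueError(f"missing gamma traces for recruited MUs {missing}")
    shapes = {np.asarray(mu_traces[i]).shape for i in recruited}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent trace shapes: {shapes}")
    weights = pool.weights
    out = None
    for i in recruited:
        term = weights[i] * np.asarray(mu_traces[i], dtype=float)
        out = term if out is None else out + term
    return out
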