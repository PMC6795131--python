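import math

import numpy as np
import pytest

from emdsim.config import PoolConfig
from emdsim.motor_pool import (
    CANONICAL_SIZES_225_10,
    MotorUnitPool,
    build_pool,
    pool_activation,
    recruitment_schedule,
)

PAPER_POOL = PoolConfig(n_fibers=225, n_mu=10, recruited_mu=10)


class TestBuildPool:
    def test_canonical_sizes_sum_to_225(self):
        assert sum(CANONICAL_SIZES_225_10) == 225

    def test_smallest_six_units_hold_33_fibers(self):
        pool = build_pool(PAPER_POOL)
        assert sum(pool.sizes[:6]) == 33
        assert sum(pool.sizes[:6]) / pool.n_fibers == pytest.approx(0.1467,
                                                                   abs=2e-4)

    def test_all_units_hold_everything(self):
        pool = build_pool(PAPER_POOL)
        assert pool.n_fibers == 225
        assert pool.weights.sum() == pytest.approx(1.0)

    def test_generic_pool_is_exponential_and_exact(self):
        pool = build_pool(PoolConfig(n_fibers=100, n_mu=5, recruited_mu=5))
        assert pool.n_fibers == 100
        assert list(pool.sizes) == sorted(pool.sizes)
        assert all(s >= 1 for s in pool.sizes)

    def test_henneman_order_enforced(self):
        with pytest.raises(ValueError):
            MotorUnitPool(sizes=(5, 3, 2))


class TestRecruitmentSchedule:
    def test_all_synchronous(self):
        pool = recruitment_schedule(build_pool(PAPER_POOL), 10, 0.0)
        assert all(t == 0.0 for t in pool.stim_times)

    def test_subset_recruits_smallest_first(self):
        pool = recruitment_schedule(build_pool(PAPER_POOL), 6, 0.0)
        recruited = [i for i, t in enumerate(pool.stim_times)
                     if math.isfinite(t)]
        assert recruited == [0, 1, 2, 3, 4, 5]
        frac = sum(pool.sizes[i] for i in recruited) / pool.n_fibers
        assert frac == pytest.approx(0.1467, abs=2e-4)

    def test_progressive_last_unit_time(self):
        pool = recruitment_schedule(build_pool(PAPER_POOL), 10, 10.0)
        assert pool.stim_times[-1] == pytest.approx(90.0)

    def test_invalid_arguments(self):
        pool = build_pool(PAPER_POOL)
        with pytest.raises(ValueError):
            recruitment_schedule(pool, 0, 0.0)
        with pytest.raises(ValueError):
            recruitment_schedule(pool, 5, -1.0)


class TestPoolActivation:
    def _pool(self, recruited, delay=0.0):
        return recruitment_schedule(build_pool(PAPER_POOL), recruited, delay)

    def test_identical_traces_average_to_themselves(self):
        pool = self._pool(10)
        trace = np.sin(np.linspace(0, 1, 50)) ** 2
        out = pool_activation({i: trace for i in range(10)}, pool)
        assert np.allclose(out, trace)

    def test_single_unit_scales_by_its_weight(self):
        pool = MotorUnitPool(
            sizes=CANONICAL_SIZES_225_10,
            stim_times=tuple([0.0] + [math.inf] * 9),
        )
        trace = np.ones(20)
        out = pool_activation({0: trace}, pool)
        assert np.allclose(out, 1.0 / 225.0)

    def test_matches_per_fiber_brute_force(self):
        rng = np.random.default_rng(0)
        pool = self._pool(10, delay=5.0)
        traces = {i: rng.random(30) for i in range(10)}
        out = pool_activation(traces, pool)
        fibers = []
        for i, size in enumerate(pool.sizes):
            fibers.extend([traces[i]] * size)
        brute = np.mean(fibers, axis=0)
        assert np.allclose(out, brute)

    def test_missing_trace_raises(self):
        pool = self._pool(10)
        with pytest.raises(ValueError, match="missing"):
            pool_activation({0: np.ones(5)}, pool)
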