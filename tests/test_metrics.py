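import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chainabm import (Direction, DirectionalDistribution, EcmParams,
                      PersistenceRecord, Simulation, detect_chain,
                      run_simulation, sequential_pair, velocity_ok)
from chainabm import _engine
from chainabm.metrics import PersistenceCounter


class TestSequentialPair:
    @pytest.mark.parametrize("a,b,expected", [
        ((10, 20), (11, 20), True),     # adjacent
        ((10, 20), (14, 20), True),     # three empty sites between
        ((10, 20), (15, 20), False),    # four empty x-sites
        ((10, 20), (11, 21), True),     # diagonal-ish, no empty y-site
        ((10, 20), (11, 22), False),    # one empty y-site
    ])
    def test_examples(self, a, b, expected):
        assert sequential_pair(a, b) is expected
        assert sequential_pair(b, a) is expected


def longest_chain_oracle(pos):
    """Independent oracle: exhaustive depth-first enumeration of every
    front-to-back (non-increasing x) simple path whose consecutive
    members are sequential pairs; returns the longest length found."""
    n = len(pos)
    nbrs = [[j for j in range(n) if j != i and pos[j][0] <= pos[i][0]
             and sequential_pair(pos[i], pos[j])] for i in range(n)]
    best = 1

    def extend(last, visited, depth):
        nonlocal best
        best = max(best, depth)
        for j in nbrs[last]:
            if not visited & (1 << j):
                extend(j, visited | (1 << j), depth + 1)

    for i in range(n):
        extend(i, 1 << i, 1)
    return best


class TestDetectChain:
    def test_contiguous_row_is_a_chain(self):
        pos = [(x, 22) for x in range(1, 9)]
        res = detect_chain(pos)
        assert res.is_chain and len(res.members) == 8
        # members come front (max x) to back
        xs = [pos[i][0] for i in res.members]
        assert xs == sorted(xs, reverse=True)

    def test_split_groups_are_not_a_chain(self):
        pos = [(x, 22) for x in range(1, 5)] + [(x, 22) for x in range(9, 13)]
        assert not detect_chain(pos).is_chain

    def test_straggler_does_not_destroy_the_chain(self):
        pos = [(x, 22) for x in range(1, 8)] + [(30, 40)]
        res = detect_chain(pos)
        assert res.is_chain and len(res.members) == 7

    @pytest.mark.parametrize("n", range(1, 6))
    def test_five_or_fewer_agents_never_chain(self, n):
        assert not detect_chain([(x, 22) for x in range(n)]).is_chain

    def test_agrees_with_oracle_on_random_placements(self, rng):
        """detect_chain and the compiled kernel both match the exhaustive
        path-enumeration oracle on 10^4 random 8-agent placements."""
        mask = np.zeros(8, np.bool_)
        for _ in range(10_000):
            flat = rng.choice(15 * 7, size=8, replace=False)
            pos = [(int(f // 7), int(f % 7)) for f in flat]
            expected = longest_chain_oracle(pos)
            got = len(detect_chain(pos).members)
            ax = np.array([p[0] for p in pos], np.int64)
            ay = np.array([p[1] for p in pos], np.int64)
            kernel = _engine._chain_mask(ax, ay, mask)
            assert got == expected == kernel

    @given(st.integers(-30, 30), st.integers(-30, 30),
           st.lists(st.tuples(st.integers(0, 14), st.integers(0, 9)),
                    min_size=6, max_size=8, unique=True))
    @settings(max_examples=200, deadline=None)
    def test_translation_and_reflection_invariance(self, dx, dy, pos):
        base = len(detect_chain(pos).members)
        shifted = [(x + dx, y + dy) for x, y in pos]
        reflected = [(x, -y) for x, y in pos]
        assert len(detect_chain(shifted).members) == base
        assert len(detect_chain(reflected).members) == base

    @given(st.lists(st.tuples(st.integers(0, 14), st.integers(0, 9)),
                    min_size=7, max_size=8, unique=True))
    @settings(max_examples=200, deadline=None)
    def test_adding_an_agent_never_shrinks_the_chain(self, pos):
        assert (len(detect_chain(pos).members)
                >= len(detect_chain(pos[:-1]).members))


class TestVelocity:
    def test_boundary_speed_passes_every_checkpoint(self):
        hist = [0.1 * t for t in range(0, 41)]
        assert all(velocity_ok(hist, t) for t in (10, 20, 30, 40))

    def test_stationary_fails_from_first_checkpoint(self):
        hist = [5.0] * 41
        assert velocity_ok(hist, 9)
        assert not velocity_ok(hist, 10)

    def test_slightly_slow_window_fails(self):
        hist = [0.09 * t for t in range(0, 11)]
        assert not velocity_ok(hist, 10)

    def test_verdict_carries_between_checkpoints(self):
        hist = [float(t) for t in range(11)] + [10.0] * 10
        assert velocity_ok(hist, 15)          # last checkpoint (t=10) passed
        assert not velocity_ok(hist + [10.0] * 10, 25)


class TestPersistenceAccounting:
    def test_scripted_block_march_counts_every_step(self):
        """A rigid 8-agent block moving one site distal per step for 50
        steps persists for all 50."""
        pos = [(x, 22) for x in range(1, 9)]
        counter = PersistenceCounter(pos, grid_width=150, max_steps=50)
        for t in range(1, 51):
            pos = [(x + 1, y) for x, y in pos]
            counter.update(pos)
        assert counter.persistence == 50
        assert counter.terminated and counter.termination_reason == "max_steps"

    def test_stationary_agents_fail_velocity_at_ten(self):
        pos = [(x, 22) for x in range(1, 9)]
        counter = PersistenceCounter(pos, grid_width=150, max_steps=100)
        while not counter.terminated:
            counter.update(pos)
        assert counter.termination_reason == "velocity_failed"
        assert counter.t == 10
        assert counter.persistence == 9

    def test_all_none_distributions_cap_persistence(self):
        none = DirectionalDistribution.point(Direction.NONE)
        rec = run_simulation("ecm", EcmParams(ldd=none, fdd=none), seed=5)
        assert rec.persistence <= 10
        assert rec.termination_reason == "velocity_failed"

    def test_record_validates_persistence_bounds(self):
        with pytest.raises(ValueError):
            PersistenceRecord(model="ecm", seed=0, persistence=5, steps=4,
                              termination_reason="max_steps",
                              final_centroid_x=1.0)

    def test_cumulative_mode_counts_resumed_chains(self):
        """Cumulative accounting never yields less persistence than the
        strict mode for the same seed."""
        for seed in range(5):
            strict = run_simulation("ecm", EcmParams(), seed=seed)
            cumul = run_simulation("ecm", EcmParams(), seed=seed,
                                   cumulative=True)
            assert cumul.persistence >= strict.persistence
            assert cumul.steps >= strict.steps
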