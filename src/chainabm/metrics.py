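"""The formal chain definition, the minimum-velocity criterion, and
chain-persistence accounting.

A chain is at least six *sequential* agents moving together toward the
target.  Two agents are sequential when there is no empty site between
them along the anterior-posterior axis (|dy| <= 1) and at most three
empty sites along the proximal-distal axis (|dx| <= 4); the chain is the
longest front-to-back sequence (ordered by non-increasing x) whose
consecutive members are sequential.  The minimum velocity is a collective
displacement toward the target of one site every 10th time step, checked
against the chain centroid at checkpoints t = 10, 20, ...

Chain persistence is the number of time steps the agents travelled as a
chain.  In the default (strict) accounting the simulation ends when
either criterion first fails — the migratory pattern has broken; the
cumulative mode instead keeps simulating and counts non-consecutive
chain steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine

#: sequential-pair windows (sites)
MAX_X_SEPARATION = 4   # three empty sites between
MAX_Y_SEPARATION = 1   # no empty site between
MIN_CHAIN_AGENTS = 6
VELOCITY_WINDOW = 10   # steps
VELOCITY_SITES = 1.0   # minimum centroid advance per window

TERMINATION_NAMES = {
    _engine.TERM_MAX_STEPS: "max_steps",
    _engine.TERM_CHAIN_BROKEN: "chain_broken",
    _engine.TERM_TARGET_REACHED: "target_reached",
    _engine.TERM_VELOCITY_FAILED: "velocity_failed",
}


def sequential_pair(a, b) -> bool:
    """Are two agent positions sequential (chain-linkable)?"""
    return (abs(a[0] - b[0]) <= MAX_X_SEPARATION
            and abs(a[1] - b[1]) <= MAX_Y_SEPARATION)


@dataclass(frozen=True)
class ChainAssessment:
    is_chain: bool
    members: tuple[int, ...]   # agent ids, front (max x) to back
    timestamp: int = 0


def detect_chain(agents, timestamp: int = 0) -> ChainAssessment:
    """Find the longest front-to-back chain among the agents.

    ``agents`` is a sequence of (x, y) positions or of objects with a
    ``position`` attribute.  A chain is a sequence of distinct agents
    ordered front to back (non-increasing x) whose consecutive members
    are sequential; agents that do not fit are skipped, so a straggler
    never destroys a chain formed by the others.  Exact dynamic
    programming over (member set, last agent) states, mirroring the
    simulation kernel bit for bit (including the tie-break between
    equally long chains).
    """
    pos = [getattr(a, "position", a) for a in agents]
    n = len(pos)
    if n == 0:
        raise ValueError("detect_chain needs at least one agent")
    size = 1 << n
    dp = [[False] * n for _ in range(size)]
    for i in range(n):
        dp[1 << i][i] = True
    for m in range(1, size):
        row = dp[m]
        for last in range(n):
            if not row[last]:
                continue
            for j in range(n):
                if not (m >> j) & 1 and pos[j][0] <= pos[last][0] \
                        and sequential_pair(pos[j], pos[last]):
                    dp[m | (1 << j)][j] = True
    best, best_m = 0, 0
    for m in range(1, size):
        if any(dp[m]):
            c = m.bit_count()
            if c > best:
                best, best_m = c, m
    ids = [i for i in range(n) if (best_m >> i) & 1]
    members = tuple(sorted(ids, key=lambda i: (-pos[i][0], pos[i][1], i)))
    return ChainAssessment(is_chain=best >= MIN_CHAIN_AGENTS,
                           members=members, timestamp=timestamp)


def velocity_ok(history, t: int) -> bool:
    """Minimum-velocity verdict at step ``t`` given the per-step centroid
    history (``history[s]`` = chain centroid x after step s).

    Evaluated at checkpoints t = 10, 20, ...; between checkpoints the
    last checkpoint's verdict carries over, and the verdict is true
    before the first checkpoint.
    """
    cp = (t // VELOCITY_WINDOW) * VELOCITY_WINDOW
    if cp < VELOCITY_WINDOW:
        return True
    return bool(history[cp] - history[cp - VELOCITY_WINDOW] >= VELOCITY_SITES)


@dataclass(frozen=True)
class PersistenceRecord:
    """Outcome of one simulation."""

    model: str
    seed: int
    persistence: int
    steps: int
    termination_reason: str
    final_centroid_x: float

    def __post_init__(self):
        if not 0 <= self.persistence <= self.steps:
            raise ValueError("persistence outside [0, steps]")


class PersistenceCounter:
    """Step-by-step persistence accounting, mirroring the run kernel.

    Feed positions after every step via :meth:`update`; read
    ``persistence``, ``terminated`` and ``termination_reason``.
    """

    def __init__(self, positions, grid_width: int, max_steps: int,
                 cumulative: bool = False):
        self.width = grid_width
        self.max_steps = max_steps
        self.cumulative = cumulative
        self.persistence = 0
        self.t = 0
        self.vel_ok = True
        self.terminated = False
        self.termination_reason = "max_steps"
        self.centroids = [self._centroid(positions)]

    @staticmethod
    def _centroid(positions):
        pos = [getattr(p, "position", p) for p in positions]
        chain = detect_chain(pos)
        xs = [pos[i][0] for i in chain.members] if chain.is_chain \
            else [p[0] for p in pos]
        return float(np.mean(xs))

    def update(self, positions) -> bool:
        """Account for one completed step; returns False once the run
        has terminated."""
        if self.terminated:
            raise RuntimeError("counter already terminated")
        self.t += 1
        pos = [getattr(p, "position", p) for p in positions]
        chain = detect_chain(pos, timestamp=self.t)
        if chain.is_chain:
            self.centroids.append(
                float(np.mean([pos[i][0] for i in chain.members])))
        else:
            self.centroids.append(float(np.mean([p[0] for p in pos])))
            if not self.cumulative:
                self.terminated = True
                self.termination_reason = "chain_broken"
                return False
        if self.t % VELOCITY_WINDOW == 0:
            self.vel_ok = velocity_ok(self.centroids, self.t)
            if not self.vel_ok and not self.cumulative:
                self.terminated = True
                self.termination_reason = "velocity_failed"
                return False
        if chain.is_chain and self.vel_ok:
            self.persistence += 1
        if any(p[0] == self.width - 1 for p in pos):
            self.terminated = True
            self.termination_reason = "target_reached"
            return False
        if self.t >= self.max_steps:
            self.terminated = True
            self.termination_reason = "max_steps"
            return False
        return True


def run_simulation(model: str, params, seed: int, *, max_steps: int = 1000,
                   cumulative: bool = False, **kwargs) -> PersistenceRecord:
    """Run one replicate of the given model and return its record."""
    from .simulate import Simulation
    return Simulation(model, params, seed=seed, max_steps=max_steps,
                      cumulative=cumulative, **kwargs).run()
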