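"""Agent state: Leaders, Followers, filopodial protrusions and the
stochastic clocks that drive direction and protrusion changes.

Two phenotypes mirror what time-lapse imaging shows at the front and back
of neural crest chains: hairy Leaders carrying up to eight filopodial
protrusions, and polarized Followers carrying up to two protrusions
oriented along their axis of movement.  Protrusions are straight lattice
rays of at most three sites (~100 um).  Each agent owns a protrusion
change clock, and each Follower additionally a direction change clock;
clocks count down once per time step and fire at zero, resetting
uniformly on {0, ..., MDI} or {0, ..., MPI}.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .distributions import DirectionalDistribution
from .lattice import Direction, Grid

MAX_PROTRUSION_LENGTH = _engine.MAX_PROT_LEN
MAX_LEADER_PROTRUSIONS = 8
MAX_FOLLOWER_PROTRUSIONS = 2


class Role(enum.IntEnum):
    LEADER = _engine.LEADER
    FOLLOWER = _engine.FOLLOWER


@dataclass
class Protrusion:
    direction: Direction
    length: int

    def __post_init__(self):
        self.direction = Direction(self.direction)
        if self.direction == Direction.NONE:
            raise ValueError("a protrusion needs a direction")
        if not 0 <= self.length <= MAX_PROTRUSION_LENGTH:
            raise ValueError("protrusion length outside [0, 3]")

    def sites(self, origin) -> list[tuple[int, int]]:
        """Lattice sites covered by the ray (nearest first)."""
        dx, dy = self.direction.offset
        return [(origin[0] + k * dx, origin[1] + k * dy)
                for k in range(1, self.length + 1)]


@dataclass
class Agent:
    """One cell.  Leaders carry no polarized direction and no direction
    clock; those fields are meaningful for Followers only."""

    id: int
    role: Role
    position: tuple[int, int]
    polarized_direction: Direction = Direction.NONE
    direction_clock: int = 0
    protrusion_clock: int = 0
    protrusions_extended: bool = False
    protrusions: list[Protrusion] = field(default_factory=list)

    def __post_init__(self):
        self.role = Role(self.role)
        limit = (MAX_LEADER_PROTRUSIONS if self.role == Role.LEADER
                 else MAX_FOLLOWER_PROTRUSIONS)
        if len(self.protrusions) > limit:
            raise ValueError(f"{self.role.name} allows <= {limit} protrusions")
        if self.direction_clock < 0 or self.protrusion_clock < 0:
            raise ValueError("clocks are non-negative counters")

    @property
    def is_leader(self) -> bool:
        return self.role == Role.LEADER

    def protrusion_sites(self) -> set[tuple[int, int]]:
        return set(itertools.chain.from_iterable(
            p.sites(self.position) for p in self.protrusions))


def _axis_protrusions(role: Role, pol: Direction,
                      length: int = 1) -> list[Protrusion]:
    """Fresh (just-extended) protrusions: one-site rays that will grow one
    site per step toward the three-site maximum.  Leaders are hairy (all
    eight directions); a polarized Follower extends at its leading edge."""
    if role == Role.LEADER:
        return [Protrusion(Direction(d), length) for d in range(8)]
    if pol == Direction.NONE:
        return []
    return [Protrusion(pol, length)]


def init_agents(n_leaders: int = 3, n_followers: int = 5,
                grid: Grid | None = None, *,
                sid: bool = False, sip: bool = False,
                fdd: DirectionalDistribution | None = None,
                mdi: int = 5, mpi: int = 5,
                rng: np.random.Generator | None = None,
                contact: bool = True) -> tuple[list[Agent], Grid]:
    """Place the initial chain and return (agents, grid).

    Agents sit single-file on the grid's mid-height row at x = 1..n with
    Leaders distal-most, and their sites become Occupied.  For the
    contact machinery (``contact=True``) every agent starts in the
    extended-protrusion phase; SID starts every Follower polarized distal
    with a shared direction-clock value, SIP gives every agent a shared
    protrusion-clock value.  Without synchronization, initial directions
    are drawn from FDD and clocks independently from U{0..MDI}/U{0..MPI}.
    """
    if n_leaders < 0 or n_followers < 0 or n_leaders + n_followers < 1:
        raise ValueError("need a positive number of agents")
    grid = grid if grid is not None else Grid()
    n = n_leaders + n_followers
    if n + 1 >= grid.width:
        raise ValueError("chain does not fit on the grid row")
    rng = rng if rng is not None else np.random.default_rng()
    fdd = fdd if fdd is not None else DirectionalDistribution.uniform()
    row = grid.height // 2
    agents = []
    for k in range(n):
        role = Role.FOLLOWER if k < n_followers else Role.LEADER
        agents.append(Agent(id=k, role=role, position=(1 + k, row)))
        grid.occupy((1 + k, row))
    if contact:
        common_d = int(rng.integers(0, mdi + 1))
        common_p = int(rng.integers(0, mpi + 1))
        for a in agents:
            if a.role == Role.FOLLOWER:
                if sid:
                    a.polarized_direction = Direction.DISTAL
                    a.direction_clock = common_d
                else:
                    a.polarized_direction = fdd.sample(rng)
                    a.direction_clock = int(rng.integers(0, mdi + 1))
            a.protrusion_clock = (common_p if sip
                                  else int(rng.integers(0, mpi + 1)))
            a.protrusions_extended = True
            a.protrusions = _axis_protrusions(a.role, a.polarized_direction)
    return agents, grid


def tick_clocks(agent: Agent, fdd: DirectionalDistribution,
                mdi: int, mpi: int, rng: np.random.Generator) -> Agent:
    """Advance an agent's clocks by one time step, in place.

    Counters decrement with a floor at the firing point: a counter at 0
    (or reaching 0 by this decrement) fires.  A direction-clock fire
    redraws the Follower's polarized direction from FDD and resets the
    clock on U{0..MDI}; a protrusion-clock fire toggles the protrusion
    state and resets on U{0..MPI}.  Extended protrusions grow one site
    toward the three-site maximum each step.

    This standalone form toggles without the contact-preserving PPC
    check, which needs the other agents; in-simulation clock ticks apply
    it (see :mod:`chainabm.contact`).
    """
    if agent.protrusions_extended:
        for p in agent.protrusions:
            if 0 < p.length < MAX_PROTRUSION_LENGTH:
                p.length += 1
    if agent.role == Role.FOLLOWER:
        if agent.direction_clock > 0:
            agent.direction_clock -= 1
        if agent.direction_clock == 0:
            agent.polarized_direction = fdd.sample(rng)
            agent.direction_clock = int(rng.integers(0, mdi + 1))
            if agent.protrusions_extended:
                agent.protrusions = _axis_protrusions(
                    agent.role, agent.polarized_direction)
    if agent.protrusion_clock > 0:
        agent.protrusion_clock -= 1
    if agent.protrusion_clock == 0:
        if agent.protrusions_extended:
            agent.protrusions_extended = False
            agent.protrusions = []
        else:
            agent.protrusions_extended = True
            agent.protrusions = _axis_protrusions(
                agent.role, agent.polarized_direction)
        agent.protrusion_clock = int(rng.integers(0, mpi + 1))
    return agent
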