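"""Contact Model rules: filopodial contact guidance.

Tests the hypothesis that cell-cell filopodial interactions direct
trailing cells to follow a lead cell.  Agents extend and retract
protrusions under stochastic clocks; before moving, an agent determines
whether it is in contact with another agent — its filopodia touching the
other's body, or vice versa.  On contact plus a true draw from LMC/FMC
the agent attempts one step in the contact direction (a Follower also
re-polarizes to it), optionally retracting its protrusions afterwards
(LRP/FRP).  Otherwise a Leader moves by a fresh LDD draw and a Follower
by its current polarized direction.  Closed sites do not impede movement
in the pure Contact Model: ECM resistance belongs to the ECM and Hybrid
Models.
"""

from __future__ import annotations

import numpy as np

from . import _engine
from .lattice import Direction
from .params import ContactParams  # noqa: F401  (re-exported rule surface)
from .simulate import Simulation


def _check(sim: Simulation, models=("contact", "hybrid")) -> None:
    if sim.model not in models:
        raise ValueError(f"expected a {'/'.join(models)} simulation, "
                         f"got {sim.model}")


def detect_contacts(sim: Simulation,
                    agent_id: int) -> list[tuple[int, Direction]]:
    """Agents in filopodial contact with ``agent_id``.

    Returns (other agent id, contact direction) pairs, where the contact
    direction is the compass direction from the agent toward the
    contacted agent (nearest-octant rounding; integer displacements never
    tie on the octant boundaries).
    """
    _check(sim)
    ax, ay, plen = sim._ax, sim._ay, sim._plen
    out = []
    for j in range(sim.n_agents):
        if j == agent_id:
            continue
        touching = any(
            _engine._covers(ax[agent_id], ay[agent_id], d,
                            plen[agent_id, d], ax[j], ay[j])
            or _engine._covers(ax[j], ay[j], d, plen[j, d],
                               ax[agent_id], ay[agent_id])
            for d in range(8))
        if touching:
            out.append((j, Direction(_engine._octant(
                int(ax[j] - ax[agent_id]), int(ay[j] - ay[agent_id])))))
    return out


def contact_update_agent(sim: Simulation, agent_id: int) -> None:
    """Apply one Contact-rule update (movement precedence: contact move,
    then LDD/polarized move) to a single agent, in place.  In a Hybrid
    simulation the move executes through the ECM site-state gate."""
    _check(sim)
    W, H = sim._sites.shape
    _engine._contact_update_one(
        sim._sites, sim._ax, sim._ay, sim._role, sim._pol, sim._ext,
        sim._plen,
        _engine._cdf(sim._pack[_engine.P_LDD:_engine.P_LDD + 9]),
        sim._pack, W, H, agent_id, sim.model == "hybrid",
        np.empty(8, np.int64), np.empty(160, np.int64),
        np.empty(160, np.int64), np.empty(160, np.int64))


def maintain_protrusions(sim: Simulation, owner: int, direction: Direction,
                         partner: int) -> int:
    """Maintain one protrusion link after a move: with probability
    LMP-true (Leader owner) or FMP-true (Follower owner) the linking
    protrusion lengthens or shortens one site toward the partner's body,
    clamped to [0, 3]; otherwise it is unchanged and the contact may
    break.  Returns the resulting length."""
    _check(sim)
    lo = np.array([owner], np.int64)
    ld = np.array([int(direction)], np.int64)
    lp = np.array([partner], np.int64)
    _engine._maintain_links(sim._ax, sim._ay, sim._role, sim._plen,
                            sim._pack[_engine.P_FMP],
                            sim._pack[_engine.P_LMP], lo, ld, lp, 1)
    return int(sim._plen[owner, int(direction)])


def tick_clocks(sim: Simulation, agent_id: int) -> None:
    """Tick one agent's clocks inside a simulation (with the PPC
    contact-preserving retraction check)."""
    _check(sim)
    _engine._tick_clocks_one(
        sim._ax, sim._ay, sim._role, sim._pol, sim._dclock, sim._pclock,
        sim._ext, sim._plen,
        _engine._cdf(sim._pack[_engine.P_FDD:_engine.P_FDD + 9]),
        int(sim._pack[_engine.P_MDI]), int(sim._pack[_engine.P_MPI]),
        sim._pack[_engine.P_PPC], agent_id)


def contact_time_step(sim: Simulation) -> Simulation:
    """Advance a Contact simulation one full time step: tick all clocks,
    then n agent updates in scheduler order, then persistence
    accounting."""
    _check(sim, ("contact",))
    return sim.step()
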