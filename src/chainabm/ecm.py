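"""ECM Model rules: path-of-least-resistance migration.

Tests the hypothesis that trailing cells follow a path of lesser
resistance in the extracellular matrix forged by a lead cell.  When an
agent is selected it draws a direction from LDD (Leaders) or FDD
(Followers); "none" keeps it stationary.  Otherwise it inspects the
adjacent site in that direction: an Occupied or out-of-bounds site
cancels the move; a Closed site is entered only when false is drawn from
POS (the force needed to forge into intact ECM); an Open site is entered
freely, and when the next site in the same direction is also Open a true
draw from ATS grants one additional step — moving faster along an open
channel.
"""

from __future__ import annotations

from . import _engine
from .params import EcmParams  # noqa: F401  (re-exported rule surface)
from .simulate import Simulation


def _check(sim: Simulation, models) -> None:
    if sim.model not in models:
        raise ValueError(f"expected a {'/'.join(models)} simulation, "
                         f"got {sim.model}")


def ecm_update_agent(sim: Simulation, agent_id: int) -> None:
    """Apply one ECM-rule update to a single agent, in place.

    Draws from the simulation's random stream; use degenerate
    distributions (or re-seed via ``chainabm._engine.seed_engine``) to
    force a branch.
    """
    _check(sim, ("ecm",))
    pack = sim._pack
    W, H = sim._sites.shape
    _engine._ecm_update_one(
        sim._sites, sim._ax, sim._ay, sim._role,
        _engine._cdf(pack[_engine.P_LDD:_engine.P_LDD + 9]),
        _engine._cdf(pack[_engine.P_FDD:_engine.P_FDD + 9]),
        pack[_engine.P_POS], pack[_engine.P_ATS], W, H, agent_id)


def ecm_time_step(sim: Simulation) -> Simulation:
    """Advance an ECM simulation one full time step (n agent updates in
    scheduler order) including persistence accounting."""
    _check(sim, ("ecm",))
    return sim.step()
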