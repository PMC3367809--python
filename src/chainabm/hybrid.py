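"""Hybrid ECM-Contact Model.

Combines the two hypotheses: agents decide *where* to move by the
Contact Model rules (contact-induced movement takes precedence over
LDD/polarized movement) but the chosen direction is executed through the
ECM Model's site-state gate — Occupied blocks, Closed requires a false
POS draw, Open moves freely with an ATS double-step through two
contiguous Open sites (contact-induced moves included).  A POS veto
leaves the agent in place for the step; there is no fallback decision.
"""

from __future__ import annotations

from .contact import contact_update_agent
from .params import HybridParams  # noqa: F401  (re-exported rule surface)
from .simulate import Simulation


def hybrid_update_agent(sim: Simulation, agent_id: int) -> None:
    """Apply one Hybrid-rule update to a single agent, in place."""
    if sim.model != "hybrid":
        raise ValueError(f"expected a hybrid simulation, got {sim.model}")
    contact_update_agent(sim, agent_id)


def hybrid_time_step(sim: Simulation) -> Simulation:
    """Advance a Hybrid simulation one full time step."""
    if sim.model != "hybrid":
        raise ValueError(f"expected a hybrid simulation, got {sim.model}")
    return sim.step()
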