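import numpy as np
import pytest
from scipy import stats as sps

from chainabm import ContactParams, Direction, DirectionalDistribution, Simulation
from chainabm import _engine
from chainabm.contact import (contact_update_agent, detect_contacts,
                              maintain_protrusions, tick_clocks)

DISTAL = DirectionalDistribution.point(Direction.DISTAL)


def contact_sim(seed=0, **kw):
    return Simulation("contact", ContactParams(**kw), seed=seed)


def forge(sim, positions, pols=None):
    """Place the agents at explicit positions with no protrusions (tests
    then add exactly the rays they need)."""
    sim._sites[:] = _engine.CLOSED
    for i, (x, y) in enumerate(positions):
        sim._ax[i], sim._ay[i] = x, y
        sim._sites[x, y] = _engine.OCCUPIED
    sim._plen[:] = 0
    sim._ext[:] = False
    if pols is not None:
        for i, p in enumerate(pols):
            sim._pol[i] = int(p)
    return sim


def park(rest):
    """Out-of-the-way positions for agents not under test."""
    return [(40 + 5 * i, 40) for i in range(rest)]


class TestContactDetection:
    def test_protrusion_ray_makes_contact(self):
        sim = forge(contact_sim(), [(5, 22), (8, 22)] + park(6))
        sim._plen[0, Direction.DISTAL] = 3      # covers (6..8, 22)
        assert detect_contacts(sim, 0) == [(1, Direction.DISTAL)]
        # contact is mutual: the other agent is touched by the ray
        assert detect_contacts(sim, 1) == [(0, Direction.PROXIMAL)]

    def test_three_site_reach_cannot_span_four_sites(self):
        sim = forge(contact_sim(), [(5, 22), (9, 22)] + park(6))
        sim._plen[0, Direction.DISTAL] = 3
        sim._plen[1, Direction.PROXIMAL] = 3
        assert detect_contacts(sim, 0) == []

    def test_retracted_protrusions_make_no_contact(self):
        sim = forge(contact_sim(), [(5, 22), (6, 22)] + park(6))
        assert detect_contacts(sim, 0) == []

    @pytest.mark.parametrize("dx,dy,expected", [
        (3, 1, Direction.DISTAL),
        (2, 2, Direction.DISTAL_POSTERIOR),
        (-1, 2, Direction.PROXIMAL_POSTERIOR),
        (0, -5, Direction.ANTERIOR),
        (1, -1, Direction.DISTAL_ANTERIOR),
    ])
    def test_octant_rounding(self, dx, dy, expected):
        assert Direction(_engine._octant(dx, dy)) == expected


class TestContactMovement:
    def test_leader_contact_move_then_forced_retraction(self):
        sim = forge(contact_sim(lmc=1.0, lrp=1.0),
                    [(5, 22)] * 0 + park(5) + [(5, 22), (30, 10), (8, 22)])
        # agent 5 (leader) at (5,22); agent 7 (leader) at (8,22)
        sim._plen[5, Direction.DISTAL] = 3
        contact_update_agent(sim, 5)
        assert sim.positions[5] == (6, 22)       # one step toward contact
        assert sim._plen[5].sum() == 0           # retracted afterwards
        assert not sim._ext[5]

    def test_follower_contact_move_repolarizes(self):
        sim = forge(contact_sim(fmc=1.0, frp=0.0),
                    [(5, 22)] + park(4) + [(30, 10), (31, 10), (8, 22)],
                    pols=[Direction.ANTERIOR])
        sim._plen[7, Direction.PROXIMAL] = 3     # leader ray touches follower
        contact_update_agent(sim, 0)
        assert sim.positions[0] == (6, 22)
        assert Direction(sim._pol[0]) == Direction.DISTAL

    def test_fmc_zero_falls_back_to_polarized_move(self):
        sim = forge(contact_sim(fmc=0.0),
                    [(5, 22)] + park(4) + [(30, 10), (31, 10), (8, 22)],
                    pols=[Direction.POSTERIOR])
        sim._plen[7, Direction.PROXIMAL] = 3
        contact_update_agent(sim, 0)
        assert sim.positions[0] == (5, 23)

    def test_unpolarized_follower_without_contact_stays(self):
        sim = forge(contact_sim(), [(5, 22)] + park(7),
                    pols=[Direction.NONE])
        for _ in range(20):
            contact_update_agent(sim, 0)
        assert sim.positions[0] == (5, 22)

    def test_occupied_destination_cancels_contact_move(self):
        sim = forge(contact_sim(lmc=1.0),
                    park(5) + [(5, 22), (6, 22), (8, 22)])
        sim._plen[5, Direction.DISTAL] = 3       # contact with (6,22)
        contact_update_agent(sim, 5)
        assert sim.positions[5] == (5, 22)


class TestMaintainProtrusions:
    def _pair(self, owner_pos, partner_pos, length, **kw):
        sim = forge(contact_sim(fmp=1.0, lmp=1.0, **kw),
                    [owner_pos, partner_pos] + park(6))
        sim._plen[0, Direction.DISTAL] = length
        return sim

    def test_partner_moved_away_ray_lengthens(self):
        sim = self._pair((5, 22), (8, 22), 2)     # tip at 7, partner at k=3
        assert maintain_protrusions(sim, 0, Direction.DISTAL, 1) == 3

    def test_clamp_at_three_sites_breaks_contact(self):
        sim = self._pair((5, 22), (9, 22), 3)     # partner at k=4
        assert maintain_protrusions(sim, 0, Direction.DISTAL, 1) == 3

    def test_partner_moved_closer_ray_shortens(self):
        sim = self._pair((5, 22), (7, 22), 3)     # partner at k=2
        assert maintain_protrusions(sim, 0, Direction.DISTAL, 1) == 2

    def test_false_draw_leaves_length_unchanged(self):
        sim = forge(contact_sim(fmp=0.0, lmp=0.0),
                    [(5, 22), (8, 22)] + park(6))
        sim._plen[0, Direction.DISTAL] = 2
        assert maintain_protrusions(sim, 0, Direction.DISTAL, 1) == 2


class TestProtrusionDynamics:
    def test_ppc_preserves_contact_mediating_ray(self):
        """A protrusion-retraction event with PPC-true = 1 spares exactly
        the rays holding a contact."""
        sim = forge(contact_sim(ppc=1.0, mpi=50), park(5) +
                    [(5, 22), (30, 10), (7, 22)])
        sim._ext[5] = True
        sim._plen[5, Direction.DISTAL] = 2       # touches (7,22)
        sim._plen[5, Direction.ANTERIOR] = 2     # touches nothing
        sim._pclock[5] = 0                       # fires on next tick
        tick_clocks(sim, 5)
        assert sim._plen[5, Direction.DISTAL] > 0
        assert sim._plen[5, Direction.ANTERIOR] == 0
        assert not sim._ext[5]

    def test_bounds_hold_during_simulation(self):
        sim = contact_sim(seed=11, mdi=3, mpi=2, lmc=0.7, fmc=0.3)
        for _ in range(60):
            if sim.done:
                break
            sim.step()
            assert sim._plen.min() >= 0 and sim._plen.max() <= 3
            n_rays = (sim._plen > 0).sum(axis=1)
            for i in range(sim.n_agents):
                cap = 8 if sim._role[i] == _engine.LEADER else 2
                assert n_rays[i] <= cap

    def test_follower_displacement_independent_of_protrusion_schedule(self):
        """With FMC = LMC = 0 nobody moves in response to contact, so the
        follower displacement distribution is unchanged by the protrusion
        clock regime (two-sample KS)."""
        def displacements(mpi, n=200):
            out = []
            for s in range(n):
                sim = Simulation(
                    "contact",
                    ContactParams(lmc=0.0, fmc=0.0, mdi=3, mpi=mpi),
                    seed=10_000 + s, max_steps=15, cumulative=True)
                x0 = sim.positions[0][0]
                while not sim.done:
                    sim.step()
                out.append(sim.positions[0][0] - x0)
            return np.array(out)

        ks = sps.ks_2samp(displacements(0), displacements(50))
        assert ks.pvalue > 0.01
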