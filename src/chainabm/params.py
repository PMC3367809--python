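"""Model parameter sets and their validity invariants.

The notation PARAMETER-value denotes the probability of drawing a value
from a parameter's distribution (e.g. POS-false, LDD-distal).  Default
values follow the default-baseline convention: every probability
distribution uniform, Boolean distributions at 50% true, discrete
integers at 5, discrete Booleans false.

Observation-to-parameter mapping (from in vivo imaging of neural crest
chains):

LDD / FDD   Leader / Follower Directionality Distribution — directional
            bias of each phenotype, a proxy for chemotactic response.
POS         Prefer an Open Site — an agent moves into a Closed (never
            yet occupied) site only when false is drawn: the willingness
            to exert force to forge into intact ECM.
ATS         Advance Two Sites in open track — conditional faster
            movement through a pre-opened channel.
LMC / FMC   Leader / Follower Move towards Contact — cells have been
            observed to change direction to move towards filopodial
            contacts.
FRP / LRP   Follower / Leader Retract Protrusions — filopodia sometimes
            retract after a cell moves towards a contacted cell.
FMP / LMP   Follower / Leader Maintain Protrusions — filopodia lengthen
            or shorten between two linked cells as one moves away from
            or towards the other.
PPC         Persist Protrusion Contact — a retraction event spares
            protrusions currently mediating a contact.
SID         Synchronize Initial Directions — trailing cells tend to be
            polarized in the direction of migration: start every
            Follower polarized distal with a shared direction clock.
SIP         Synchronize Initial Protrusions — shared initial protrusion
            clock for all agents.
MDI / MPI   Maximum Direction / Protrusion Interval, the clock-reset
            ranges (integers in [0, 50]).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from . import _engine
from .distributions import (BooleanDistribution, DirectionalDistribution,
                            as_boolean, as_directional)

MAX_CLOCK_INTERVAL = 50


def _u() -> DirectionalDistribution:
    return DirectionalDistribution.uniform()


def _half() -> BooleanDistribution:
    return BooleanDistribution(0.5)


@dataclass(frozen=True)
class EcmParams:
    """The four ECM Model parameters plus the track flag."""

    ldd: DirectionalDistribution = field(default_factory=_u)
    fdd: DirectionalDistribution = field(default_factory=_u)
    pos: BooleanDistribution = field(default_factory=_half)
    ats: BooleanDistribution = field(default_factory=_half)
    track_present: bool = True

    model = "ecm"

    def __post_init__(self):
        object.__setattr__(self, "ldd", as_directional(self.ldd))
        object.__setattr__(self, "fdd", as_directional(self.fdd))
        object.__setattr__(self, "pos", as_boolean(self.pos))
        object.__setattr__(self, "ats", as_boolean(self.ats))

    def pack(self) -> np.ndarray:
        p = np.zeros(_engine.PACK_LEN)
        p[_engine.P_LDD:_engine.P_LDD + 9] = self.ldd.probs
        p[_engine.P_FDD:_engine.P_FDD + 9] = self.fdd.probs
        p[_engine.P_POS] = self.pos.p_true
        p[_engine.P_ATS] = self.ats.p_true
        p[_engine.P_TRACK] = float(self.track_present)
        return p


@dataclass(frozen=True)
class ContactParams:
    """The thirteen Contact Model parameters."""

    ldd: DirectionalDistribution = field(default_factory=_u)
    fdd: DirectionalDistribution = field(default_factory=_u)
    lmc: BooleanDistribution = field(default_factory=_half)
    fmc: BooleanDistribution = field(default_factory=_half)
    ppc: BooleanDistribution = field(default_factory=_half)
    frp: BooleanDistribution = field(default_factory=_half)
    lrp: BooleanDistribution = field(default_factory=_half)
    fmp: BooleanDistribution = field(default_factory=_half)
    lmp: BooleanDistribution = field(default_factory=_half)
    sid: bool = False
    sip: bool = False
    mdi: int = 5
    mpi: int = 5

    model = "contact"

    def __post_init__(self):
        object.__setattr__(self, "ldd", as_directional(self.ldd))
        object.__setattr__(self, "fdd", as_directional(self.fdd))
        for name in ("lmc", "fmc", "ppc", "frp", "lrp", "fmp", "lmp"):
            object.__setattr__(self, name, as_boolean(getattr(self, name)))
        for name in ("mdi", "mpi"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and
                    0 <= v <= MAX_CLOCK_INTERVAL):
                raise ValueError(
                    f"{name.upper()}={v!r} must be an integer in "
                    f"[0, {MAX_CLOCK_INTERVAL}]")
            object.__setattr__(self, name, int(v))
        for name in ("sid", "sip"):
            object.__setattr__(self, name, bool(getattr(self, name)))

    def pack(self) -> np.ndarray:
        p = np.zeros(_engine.PACK_LEN)
        p[_engine.P_LDD:_engine.P_LDD + 9] = self.ldd.probs
        p[_engine.P_FDD:_engine.P_FDD + 9] = self.fdd.probs
        p[_engine.P_LMC] = self.lmc.p_true
        p[_engine.P_FMC] = self.fmc.p_true
        p[_engine.P_PPC] = self.ppc.p_true
        p[_engine.P_FRP] = self.frp.p_true
        p[_engine.P_LRP] = self.lrp.p_true
        p[_engine.P_FMP] = self.fmp.p_true
        p[_engine.P_LMP] = self.lmp.p_true
        p[_engine.P_SID] = float(self.sid)
        p[_engine.P_SIP] = float(self.sip)
        p[_engine.P_MDI] = float(self.mdi)
        p[_engine.P_MPI] = float(self.mpi)
        return p


@dataclass(frozen=True)
class HybridParams(ContactParams):
    """Contact-Model decision logic gated by the ECM movement rules:
    the union of both parents' parameters."""

    pos: BooleanDistribution = field(default_factory=_half)
    ats: BooleanDistribution = field(default_factory=_half)
    track_present: bool = True

    model = "hybrid"

    def __post_init__(self):
        super().__post_init__()
        object.__setattr__(self, "pos", as_boolean(self.pos))
        object.__setattr__(self, "ats", as_boolean(self.ats))

    def pack(self) -> np.ndarray:
        p = super().pack()
        p[_engine.P_POS] = self.pos.p_true
        p[_engine.P_ATS] = self.ats.p_true
        p[_engine.P_TRACK] = float(self.track_present)
        return p


PARAM_CLASSES = {"ecm": EcmParams, "contact": ContactParams,
                 "hybrid": HybridParams}


def param_names(model: str) -> list[str]:
    return [f.name for f in fields(PARAM_CLASSES[model])]
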