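"""The single-simulation driver.

A :class:`Simulation` owns the lattice and agent state for one replicate
and advances it one time step at a time; :meth:`run` drives it to
termination and returns a :class:`~chainabm.metrics.PersistenceRecord`.
Each time step ticks every clock (Contact/Hybrid), then performs n agent
updates drawn uniformly with replacement (so some agents may update twice
in a step and some not at all), mirroring random occupied-site selection.

All randomness comes from one seeded Mersenne Twister stream shared with
the batch kernels, so a (model, params, seed) triple reproduces the same
trajectory whether stepped here or run by :func:`chainabm.sweep.run_replicates`.
"""

from __future__ import annotations

import numpy as np

from . import _engine
from .agents import Agent, Protrusion, Role
from .lattice import Direction, Grid
from .metrics import TERMINATION_NAMES, PersistenceCounter, PersistenceRecord
from .params import PARAM_CLASSES

MODEL_CODES = {"ecm": _engine.MODEL_ECM, "contact": _engine.MODEL_CONTACT,
               "hybrid": _engine.MODEL_HYBRID}
SCHEDULER_CODES = {"replacement": _engine.SCHED_REPLACEMENT,
                   "shuffle": _engine.SCHED_SHUFFLE}


class Simulation:
    """One replicate of the ECM, Contact or Hybrid Model.

    Parameters
    ----------
    model : {"ecm", "contact", "hybrid"}
    params : EcmParams | ContactParams | HybridParams, optional
        Defaults to the model's default baseline parameter set.
    seed : int
        Seeds the simulation's random stream.
    cumulative : bool
        Count non-consecutive chain steps instead of terminating at the
        first criterion failure.
    scheduler : {"replacement", "shuffle"}
        Agent update scheduling; "replacement" (default) draws n agents
        uniformly with replacement per step.
    """

    def __init__(self, model: str, params=None, *, seed: int = 0,
                 width: int = 150, height: int = 45,
                 n_leaders: int = 3, n_followers: int = 5,
                 max_steps: int = 1000, cumulative: bool = False,
                 scheduler: str = "replacement"):
        if model not in MODEL_CODES:
            raise ValueError(f"unknown model {model!r}")
        if params is None:
            params = PARAM_CLASSES[model]()
        if params.model != model:
            raise TypeError(f"{type(params).__name__} does not parameterize "
                            f"the {model} model")
        if n_leaders + n_followers < 1 or min(n_leaders, n_followers) < 0:
            raise ValueError("need a positive number of agents")
        if n_leaders + n_followers + 1 >= width:
            raise ValueError("chain does not fit on the grid row")
        self.model = model
        self.params = params
        self.seed = int(seed)
        self.max_steps = int(max_steps)
        self.cumulative = bool(cumulative)
        self.scheduler = scheduler
        self._code = MODEL_CODES[model]
        self._sched = SCHEDULER_CODES[scheduler]
        self._pack = params.pack()
        _engine.seed_engine(self.seed)
        (self._sites, self._ax, self._ay, self._role, self._pol,
         self._dclock, self._pclock, self._ext, self._plen) = \
            _engine.init_state(self._code, self._pack, width, height,
                               n_leaders, n_followers)
        self._counter = PersistenceCounter(self.positions, width,
                                           self.max_steps, self.cumulative)

    # -- state views --------------------------------------------------------
    @property
    def time(self) -> int:
        return self._counter.t

    @property
    def n_agents(self) -> int:
        return self._ax.size

    @property
    def positions(self) -> list[tuple[int, int]]:
        return [(int(x), int(y)) for x, y in zip(self._ax, self._ay)]

    @property
    def grid(self) -> Grid:
        """Live view of the site grid (shares state with the engine)."""
        w, h = self._sites.shape
        return Grid(w, h, _states=self._sites)

    @property
    def agents(self) -> list[Agent]:
        """Snapshot of the agents (copies; mutating them does not affect
        the simulation)."""
        out = []
        for i in range(self.n_agents):
            prot = [Protrusion(Direction(d), int(self._plen[i, d]))
                    for d in range(8) if self._plen[i, d] > 0]
            out.append(Agent(
                id=i, role=Role(int(self._role[i])),
                position=(int(self._ax[i]), int(self._ay[i])),
                polarized_direction=Direction(int(self._pol[i])),
                direction_clock=int(self._dclock[i]),
                protrusion_clock=int(self._pclock[i]),
                protrusions_extended=bool(self._ext[i]),
                protrusions=prot))
        return out

    @property
    def done(self) -> bool:
        return self._counter.terminated

    @property
    def persistence(self) -> int:
        return self._counter.persistence

    # -- dynamics -----------------------------------------------------------
    def step(self) -> "Simulation":
        """Advance one time step and update the persistence accounting."""
        if self.done:
            raise RuntimeError("simulation already terminated")
        _engine.advance(self._code, self._sites, self._ax, self._ay,
                        self._role, self._pol, self._dclock, self._pclock,
                        self._ext, self._plen, self._pack, self._sched)
        self._counter.update(self.positions)
        return self

    def run(self) -> PersistenceRecord:
        """Run to termination and return the persistence record."""
        while not self.done:
            self.step()
        return self.record

    @property
    def record(self) -> PersistenceRecord:
        if not self.done:
            raise RuntimeError("simulation still running")
        return PersistenceRecord(
            model=self.model, seed=self.seed,
            persistence=self._counter.persistence,
            steps=self._counter.t,
            termination_reason=self._counter.termination_reason,
            final_centroid_x=float(np.mean(self._ax)))


def run_one_fast(model: str, params, seed: int, *, width: int = 150,
                 height: int = 45, n_leaders: int = 3, n_followers: int = 5,
                 max_steps: int = 1000, cumulative: bool = False,
                 scheduler: str = "replacement") -> PersistenceRecord:
    """Kernel-side equivalent of ``Simulation(...).run()`` (identical
    trajectory and record for the same arguments, without materializing
    per-step Python state)."""
    pers, term, steps, cx = _engine.run_one(
        MODEL_CODES[model], params.pack(), width, height, n_leaders,
        n_followers, max_steps, cumulative, SCHEDULER_CODES[scheduler],
        seed)
    return PersistenceRecord(model=model, seed=int(seed),
                             persistence=int(pers), steps=int(steps),
                             termination_reason=TERMINATION_NAMES[int(term)],
                             final_centroid_x=float(cx))
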