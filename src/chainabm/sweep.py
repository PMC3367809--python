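"""Replicate batches and parameter-space exploration.

Because the models are stochastic, every parameter set is judged by the
mean chain persistence over many replicate simulations (400 by default)
with independent seeds derived from one master seed.  The ECM parameter
space is small enough to enumerate exhaustively (6400 sets on the
default grid); the Contact space is astronomically larger, so parameter
sets are sampled uniformly at random from the value grids.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _engine
from .params import ContactParams, EcmParams, HybridParams
from .simulate import MODEL_CODES, SCHEDULER_CODES

logger = logging.getLogger(__name__)

DEFAULT_REPLICATES = 400


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive n independent per-replicate seeds (< 2**31) from a master
    seed via a counter-based seed sequence; the derivation is stable, so
    recording the master seed suffices for exact replay."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return (state.astype(np.int64) & 0x7FFFFFFF)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean chain persistence +/- s.e.m. (and range) over n replicates."""

    param_id: object
    n: int
    mean: float
    sem: float
    min: int
    max: int

    def __str__(self):
        return (f"{self.param_id}: persistence {self.mean:.2f} "
                f"± {self.sem:.2f} (n={self.n}, range {self.min}-{self.max})")


def run_replicates(model: str, params, n: int = DEFAULT_REPLICATES,
                   seed: int = 0, *, param_id=None, width: int = 150,
                   height: int = 45, n_leaders: int = 3,
                   n_followers: int = 5, max_steps: int = 1000,
                   cumulative: bool = False, scheduler: str = "replacement",
                   return_raw: bool = False):
    """Run n independent replicates and summarize their persistence.

    Returns a :class:`ReplicateSummary`, or ``(summary, DataFrame)`` with
    the per-run records when ``return_raw``.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    seeds = derive_seeds(seed, n)
    pers, term, steps, cx = _engine.run_batch(
        MODEL_CODES[model], params.pack(), width, height, n_leaders,
        n_followers, max_steps, cumulative, SCHEDULER_CODES[scheduler],
        seeds)
    sem = float(pers.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    summary = ReplicateSummary(param_id=param_id, n=n,
                               mean=float(pers.mean()), sem=sem,
                               min=int(pers.min()), max=int(pers.max()))
    if not return_raw:
        return summary
    from .metrics import TERMINATION_NAMES
    raw = pd.DataFrame({
        "seed": seeds, "model": model, "persistence": pers, "steps": steps,
        "termination_reason": [TERMINATION_NAMES[int(t)] for t in term],
        "final_centroid_x": cx})
    return summary, raw


# ---------------------------------------------------------------------------
# sweep grids
# ---------------------------------------------------------------------------

def _check_levels(name, levels):
    arr = list(levels)
    if len(set(np.round(arr, 12))) != len(arr):
        raise ValueError(f"duplicate levels in {name}")
    return arr


@dataclass(frozen=True)
class SweepGrid:
    """Per-parameter value lists for a sweep.

    Directional parameters vary by their distal bias (the remaining mass
    spread equally over the other eight values); Boolean parameters by
    p_true; MDI/MPI over integer levels; SID/SIP over {False, True}.
    The default ECM grid (10 directional x 8 Boolean levels) yields
    10*10*8*8 = 6400 combinations.
    """

    directional_levels: tuple = tuple(np.linspace(1.0 / 9.0, 1.0, 10))
    boolean_levels: tuple = tuple(np.linspace(0.0, 1.0, 8))
    interval_levels: tuple = (0, 5, 10, 20, 35, 50)
    flag_levels: tuple = (False, True)
    expected_ecm_sets: int | None = 6400

    def __post_init__(self):
        for name in ("directional_levels", "boolean_levels",
                     "interval_levels"):
            object.__setattr__(self, name,
                               tuple(_check_levels(name, getattr(self, name))))

    @classmethod
    def ecm_default(cls) -> "SweepGrid":
        return cls()

    @classmethod
    def contact_default(cls) -> "SweepGrid":
        """Boolean-distribution levels 0-100% in 6 steps; MDI/MPI levels
        spanning [0, 50]."""
        return cls(boolean_levels=tuple(np.linspace(0.0, 1.0, 6)),
                   expected_ecm_sets=None)

    @property
    def n_ecm_sets(self) -> int:
        return len(self.directional_levels) ** 2 * len(self.boolean_levels) ** 2


def enumerate_ecm_grid(grid: SweepGrid | None = None,
                       track: bool = True) -> list[EcmParams]:
    """The Cartesian product of the four ECM parameters' value lists."""
    grid = grid if grid is not None else SweepGrid.ecm_default()
    if (grid.expected_ecm_sets is not None
            and grid.n_ecm_sets != grid.expected_ecm_sets):
        logger.warning("ECM grid yields %d sets, expected %d",
                       grid.n_ecm_sets, grid.expected_ecm_sets)
    out = []
    for ldd, fdd, pos, ats in itertools.product(
            grid.directional_levels, grid.directional_levels,
            grid.boolean_levels, grid.boolean_levels):
        out.append(EcmParams(ldd=float(ldd), fdd=float(fdd), pos=float(pos),
                             ats=float(ats), track_present=track))
    return out


def sample_contact_sets(n: int, grid: SweepGrid | None = None,
                        rng: np.random.Generator | None = None,
                        hybrid: bool = False, track: bool = True) -> list:
    """Sample n Contact (or Hybrid) parameter sets, each parameter drawn
    independently and uniformly from its value list."""
    if n < 1:
        raise ValueError("need at least one set")
    grid = grid if grid is not None else SweepGrid.contact_default()
    rng = rng if rng is not None else np.random.default_rng()
    dl = np.asarray(grid.directional_levels)
    bl = np.asarray(grid.boolean_levels)
    il = np.asarray(grid.interval_levels)
    fl = list(grid.flag_levels)
    out = []
    for _ in range(n):
        kw = dict(
            ldd=float(rng.choice(dl)), fdd=float(rng.choice(dl)),
            lmc=float(rng.choice(bl)), fmc=float(rng.choice(bl)),
            ppc=float(rng.choice(bl)), frp=float(rng.choice(bl)),
            lrp=float(rng.choice(bl)), fmp=float(rng.choice(bl)),
            lmp=float(rng.choice(bl)),
            sid=bool(fl[rng.integers(len(fl))]),
            sip=bool(fl[rng.integers(len(fl))]),
            mdi=int(rng.choice(il)), mpi=int(rng.choice(il)))
        if hybrid:
            out.append(HybridParams(pos=float(rng.choice(bl)),
                                    ats=float(rng.choice(bl)),
                                    track_present=track, **kw))
        else:
            out.append(ContactParams(**kw))
    return out


def params_frame(sets) -> pd.DataFrame:
    """Numeric coding of parameter sets for sub-group statistics:
    directional parameters by distal probability, Boolean distributions
    by p_true, SID/SIP as 0/1."""
    rows = []
    for p in sets:
        row = {"ldd": p.ldd.distal_p, "fdd": p.fdd.distal_p}
        for name in ("lmc", "fmc", "ppc", "frp", "lrp", "fmp", "lmp",
                     "pos", "ats"):
            if hasattr(p, name):
                row[name] = getattr(p, name).p_true
        for name in ("sid", "sip"):
            if hasattr(p, name):
                row[name] = int(getattr(p, name))
        for name in ("mdi", "mpi"):
            if hasattr(p, name):
                row[name] = getattr(p, name)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sweep drivers
# ---------------------------------------------------------------------------

def sweep(model: str, param_sets, reps: int, seed: int = 0,
          progress: bool = False, **sim_kwargs) -> pd.DataFrame:
    """Mean persistence for each parameter set (one summary row per set).

    Each set r uses replicate seeds derived from ``seed + r`` so sets are
    independent and individually replayable.
    """
    rows = []
    iterator = enumerate(param_sets)
    if progress:
        from tqdm import tqdm  # optional nicety; plain loop without it
        iterator = tqdm(iterator, total=len(param_sets), desc="sweep")
    for r, p in iterator:
        s = run_replicates(model, p, n=reps, seed=seed + r, param_id=r,
                           **sim_kwargs)
        rows.append({"param_id": r, "n": s.n, "mean": s.mean, "sem": s.sem,
                     "min": s.min, "max": s.max})
    return pd.DataFrame(rows)


def sweep_ecm(track: bool = True, grid: SweepGrid | None = None,
              screen_reps: int = 100, refine_reps: int = DEFAULT_REPLICATES,
              refine_top: float = 0.1, seed: int = 0,
              progress: bool = False) -> pd.DataFrame:
    """Exhaustive ECM sweep: screen every set at ``screen_reps``
    replicates, then re-run the top ``refine_top`` fraction at
    ``refine_reps``.  Returns one row per set with screening statistics
    and, for refined sets, the refined mean/sem in ``mean``/``sem``
    (screening values are kept in ``screen_mean``/``screen_sem``)."""
    sets = enumerate_ecm_grid(grid, track=track)
    df = sweep("ecm", sets, reps=screen_reps, seed=seed, progress=progress)
    df = df.rename(columns={"mean": "screen_mean", "sem": "screen_sem"})
    df["mean"] = df["screen_mean"]
    df["sem"] = df["screen_sem"]
    df["refined"] = False
    n_refine = max(1, int(np.ceil(refine_top * len(sets))))
    top = df.nlargest(n_refine, "screen_mean").index
    for idx in top:
        r = int(df.loc[idx, "param_id"])
        s = run_replicates("ecm", sets[r], n=refine_reps,
                           seed=seed + 1_000_000 + r, param_id=r)
        df.loc[idx, ["mean", "sem", "min", "max", "n"]] = \
            [s.mean, s.sem, s.min, s.max, s.n]
        df.loc[idx, "refined"] = True
    pf = params_frame(sets)
    return pd.concat([df.reset_index(drop=True), pf], axis=1)


def sweep_contact_random(n_sets: int = 10_000, reps: int = 100,
                         seed: int = 0, grid: SweepGrid | None = None,
                         hybrid: bool = False,
                         progress: bool = False) -> pd.DataFrame:
    """Random Contact (or Hybrid) sweep: sample ``n_sets`` parameter sets
    and evaluate each at ``reps`` replicates.  Returns one row per set
    with summary statistics and the numeric-coded parameter values."""
    rng = np.random.default_rng(seed)
    model = "hybrid" if hybrid else "contact"
    sets = sample_contact_sets(n_sets, grid, rng, hybrid=hybrid)
    df = sweep(model, sets, reps=reps, seed=seed, progress=progress)
    return pd.concat([df, params_frame(sets)], axis=1)
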