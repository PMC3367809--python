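"""Categorical samplers over movement directions and Boolean choices.

Model parameters are probability distributions: directional distributions
assign probabilities to the eight compass directions plus "none" (draw
none and the agent makes no directional decision that step), Boolean
distributions to {true, false}.  The uniform directional distribution
puts ~1/9 (11%) on every value; a "distal bias" of p puts p on distal and
spreads the remainder equally over the other eight values.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np

from .lattice import Direction

_PROB_TOL = 1e-9


class DirectionalDistribution:
    """Categorical distribution over the 9 direction values."""

    __slots__ = ("probs",)

    def __init__(self, probs):
        if isinstance(probs, Mapping):
            vec = np.zeros(9)
            for key, p in probs.items():
                d = key if isinstance(key, Direction) else \
                    Direction[str(key).upper()]
                vec[int(d)] = float(p)
        else:
            vec = np.asarray(probs, dtype=float)
            if vec.shape != (9,):
                raise ValueError("need 9 probabilities (8 directions + none)")
        if np.any(vec < 0):
            raise ValueError("negative probability")
        if abs(vec.sum() - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities sum to {vec.sum()}, not 1")
        self.probs = vec

    @classmethod
    def uniform(cls) -> "DirectionalDistribution":
        """All nine values equally likely (the default baseline)."""
        return cls(np.full(9, 1.0 / 9.0))

    @classmethod
    def distal_biased(cls, p: float) -> "DirectionalDistribution":
        """Probability ``p`` on distal, the rest spread equally over the
        other seven directions and none.  ``p = 1/9`` recovers uniform."""
        if not 0.0 <= p <= 1.0:
            raise ValueError("bias must be a probability")
        vec = np.full(9, (1.0 - p) / 8.0)
        vec[Direction.DISTAL] = p
        return cls(vec)

    @classmethod
    def point(cls, d: Direction) -> "DirectionalDistribution":
        """Degenerate distribution: always ``d``."""
        vec = np.zeros(9)
        vec[int(d)] = 1.0
        return cls(vec)

    @property
    def distal_p(self) -> float:
        return float(self.probs[Direction.DISTAL])

    def sample(self, rng: np.random.Generator) -> Direction:
        return Direction(int(rng.choice(9, p=self.probs)))

    def __eq__(self, other):
        return (isinstance(other, DirectionalDistribution)
                and bool(np.allclose(self.probs, other.probs)))

    def __repr__(self):
        parts = ", ".join(f"{Direction(i).name.lower()}={p:.3g}"
                          for i, p in enumerate(self.probs) if p > 0)
        return f"DirectionalDistribution({parts})"


class BooleanDistribution:
    """Bernoulli distribution over {true, false}."""

    __slots__ = ("p_true",)

    def __init__(self, p_true: float):
        p_true = float(p_true)
        if not 0.0 <= p_true <= 1.0:
            raise ValueError(f"p_true={p_true} outside [0, 1]")
        self.p_true = p_true

    def sample(self, rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.p_true)

    def __eq__(self, other):
        return (isinstance(other, BooleanDistribution)
                and self.p_true == other.p_true)

    def __repr__(self):
        return f"BooleanDistribution(p_true={self.p_true:.3g})"


def as_boolean(value) -> BooleanDistribution:
    """Coerce a float or mapping with ``p_true`` into a distribution."""
    if isinstance(value, BooleanDistribution):
        return value
    if isinstance(value, Mapping):
        return BooleanDistribution(value["p_true"])
    return BooleanDistribution(value)


def as_directional(value) -> DirectionalDistribution:
    """Coerce ``"uniform"``, a distal-bias float, a ``{distal_bias: p}``
    mapping, or a full value->probability mapping into a distribution."""
    if isinstance(value, DirectionalDistribution):
        return value
    if isinstance(value, str):
        if value.lower() == "uniform":
            return DirectionalDistribution.uniform()
        raise ValueError(f"unknown directional shorthand {value!r}")
    if isinstance(value, Mapping):
        if set(value) == {"distal_bias"}:
            return DirectionalDistribution.distal_biased(value["distal_bias"])
        return DirectionalDistribution(value)
    if np.isscalar(value):
        return DirectionalDistribution.distal_biased(float(value))
    return DirectionalDistribution(value)
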