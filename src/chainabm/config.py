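"""Run configuration: YAML files in, validated RunConfig out."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .params import PARAM_CLASSES, param_names


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a batch of simulations."""

    model: str
    params: object
    n_leaders: int = 3
    n_followers: int = 5
    width: int = 150
    height: int = 45
    reps: int = 400
    max_steps: int = 1000
    seed: int = 0
    cumulative: bool = False
    scheduler: str = "replacement"

    def __post_init__(self):
        if self.model not in PARAM_CLASSES:
            raise ConfigError(f"unknown model {self.model!r}")
        if self.params.model != self.model:
            raise ConfigError(
                f"{type(self.params).__name__} does not parameterize "
                f"the {self.model} model")
        for name in ("n_leaders", "n_followers", "reps", "max_steps"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_leaders + self.n_followers < 1:
            raise ConfigError("need at least one agent")
        if self.scheduler not in ("replacement", "shuffle"):
            raise ConfigError(f"unknown scheduler {self.scheduler!r}")

    def sim_kwargs(self) -> dict:
        return dict(width=self.width, height=self.height,
                    n_leaders=self.n_leaders, n_followers=self.n_followers,
                    max_steps=self.max_steps, cumulative=self.cumulative,
                    scheduler=self.scheduler)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        p = {}
        for f in dataclasses.fields(self.params):
            v = getattr(self.params, f.name)
            if hasattr(v, "probs"):
                p[f.name] = {str(i): float(x)
                             for i, x in enumerate(v.probs) if x > 0}
            elif hasattr(v, "p_true"):
                p[f.name] = float(v.p_true)
            else:
                p[f.name] = v
        d["params"] = p
        return d


_TOP_KEYS = {"model", "params", "track", "n_leaders", "n_followers",
             "width", "height", "reps", "max_steps", "seed", "cumulative",
             "scheduler"}


def build_config(doc: dict) -> RunConfig:
    """Validate a configuration mapping (already parsed) into a
    RunConfig; every omitted key takes its documented default."""
    if not isinstance(doc, dict) or "model" not in doc:
        raise ConfigError("configuration must be a mapping with a 'model'")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    model = str(doc["model"]).lower()
    if model not in PARAM_CLASSES:
        raise ConfigError(f"unknown model {model!r}")
    pkw = dict(doc.get("params") or {})
    bad = set(pkw) - set(param_names(model))
    if bad:
        raise ConfigError(f"unknown {model} parameters: {sorted(bad)}")
    if "track" in doc:
        if "track_present" in pkw:
            raise ConfigError("give either 'track' or params.track_present")
        if "track_present" in param_names(model):
            pkw["track_present"] = bool(doc["track"])
        else:
            raise ConfigError(f"the {model} model takes no track flag")
    try:
        params = PARAM_CLASSES[model](**pkw)
    except (ValueError, KeyError, TypeError) as exc:
        raise ConfigError(f"invalid {model} parameters: {exc}") from exc
    kw = {k: doc[k] for k in _TOP_KEYS - {"model", "params", "track"}
          if k in doc}
    return RunConfig(model=model, params=params, **kw)


def load_config(path) -> RunConfig:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return build_config(doc)
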