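"""Study configuration: one YAML/JSON block driving every stage.

Defaults reproduce the study design: K = 2,000,000, B0 = 1,500,000,
Poisson(10,000) yearly effort, catch-noise SD 0.1 on the log scale, a
32-year stabilization period before 64 analyzed years with the parameter
change after year 32, the four finite parameter sets, and the five
joinpoint initialization pairs.  Unknown keys are rejected loudly so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bayes import PriorConfig
from .segmented import DEFAULT_INITS
from .simulate import R1_SET, R2_SET, Q1_SET, Q2_SET

__all__ = ["StudyConfig", "load_config", "save_config", "config_hash"]


@dataclass
class StudyConfig:
    """Validated bundle of every knob the pipeline exposes."""

    seed: int = 1
    n_sims: int = 1000
    scenarios: tuple[int, ...] = ()
    stabilization_years: int = 32
    analyzed_years: int = 64
    change_year: int = 32
    K: float = 2_000_000.0
    B0: float = 1_500_000.0
    effort_mean: float = 10_000.0
    catch_noise_var: float = 0.01
    r1_set: tuple[float, ...] = R1_SET
    r2_set: tuple[float, ...] = R2_SET
    q1_set: tuple[float, ...] = Q1_SET
    q2_set: tuple[float, ...] = Q2_SET
    joinpoint_inits: tuple[tuple[float, float], ...] = DEFAULT_INITS
    segmented_tol: float = 1e-5
    segmented_max_iter: int = 30
    segmented_n_boot: int = 10
    chains: int = 4
    draws: int = 2000
    warmup: int = 1000
    prior: PriorConfig = field(default_factory=PriorConfig)
    out_dir: str = "study_out"

    def __post_init__(self) -> None:
        if min(self.r1_set) < max(self.r2_set):
            raise ValueError(
                "r1_set/r2_set must satisfy min(r1_set) >= max(r2_set) so that "
                "r1 >= r2 holds for every draw"
            )
        for name in ("r1_set", "r2_set", "q1_set", "q2_set"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} values must be positive")
        if not (0 < self.change_year < self.analyzed_years):
            raise ValueError("change_year must lie inside the analyzed horizon")
        if self.K <= 0 or not (0 < self.B0 <= self.K):
            raise ValueError("need K > 0 and 0 < B0 <= K")
        if self.effort_mean <= 0 or self.catch_noise_var < 0:
            raise ValueError("effort_mean must be positive, catch_noise_var >= 0")
        if any(s not in (1, 2, 3) for s in self.scenarios):
            raise ValueError("scenarios must be a subset of {1, 2, 3}")

    # ------------------------------------------------------------- (de)ser

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = list(self.scenarios)
        for name in ("r1_set", "r2_set", "q1_set", "q2_set"):
            d[name] = list(d[name])
        d["joinpoint_inits"] = [list(p) for p in d["joinpoint_inits"]]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "prior" in data and not isinstance(data["prior"], PriorConfig):
            pknown = {f.name for f in dataclasses.fields(PriorConfig)}
            punknown = set(data["prior"]) - pknown
            if punknown:
                raise ValueError(f"unknown prior keys: {sorted(punknown)}")
            data["prior"] = PriorConfig(**data["prior"])
        for name in ("r1_set", "r2_set", "q1_set", "q2_set", "scenarios"):
            if name in data:
                data[name] = tuple(data[name])
        if "joinpoint_inits" in data:
            data["joinpoint_inits"] = tuple(tuple(p) for p in data["joinpoint_inits"])
        return cls(**data)

    # ------------------------------------------------------------- helpers

    def param_overrides(self) -> dict:
        """Fixed PopulationParameters fields implied by this config."""
        return {
            "K": self.K,
            "B0": self.B0,
            "change_year": self.change_year,
            "effort_mean": self.effort_mean,
            "catch_noise_var": self.catch_noise_var,
            "stabilization_years": self.stabilization_years,
        }

    def joinpoint_kwargs(self) -> dict:
        return {
            "inits": self.joinpoint_inits,
            "max_iter": self.segmented_max_iter,
            "tol": self.segmented_tol,
            "n_boot": self.segmented_n_boot,
        }

    def mcmc_kwargs(self) -> dict:
        return {"chains": self.chains, "draws": self.draws, "warmup": self.warmup}


def load_config(path) -> StudyConfig:
    """Load a YAML (or JSON) config; absent keys keep their defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return StudyConfig.from_dict(data)


def save_config(config: StudyConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: StudyConfig) -> str:
    """Stable hash of the full configuration, for run manifests."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
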