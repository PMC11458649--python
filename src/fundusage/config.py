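"""Pipeline configuration: one validated mapping for every tunable.

A config file (YAML or JSON) holds four sections — ``roi``, ``lasso``, ``cv``
and ``seed`` — all optional; anything omitted takes the documented default.
Unknown keys anywhere are rejected rather than ignored, so typos cannot
silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import RoiConfig

__all__ = ["LassoConfig", "CvConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class LassoConfig:
    alpha: float = 1.0
    lambda_strategy: str = "inner_cv"  # or "fixed"
    fixed_lambda: float | None = None
    tol: float = 1e-7
    max_iter: int = 100_000
    n_lambda: int = 50
    ratio_min: float = 1e-2
    inner_folds: int = 10

    def __post_init__(self) -> None:
        # coerce numerics: YAML 1.1 reads "1.0e6" (no signed exponent) as a string
        for name, cast in (
            ("alpha", float),
            ("tol", float),
            ("ratio_min", float),
            ("max_iter", int),
            ("n_lambda", int),
            ("inner_folds", int),
        ):
            object.__setattr__(self, name, cast(getattr(self, name)))
        if self.fixed_lambda is not None:
            object.__setattr__(self, "fixed_lambda", float(self.fixed_lambda))
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("lasso.alpha must be in [0, 1]")
        if self.lambda_strategy not in ("inner_cv", "fixed"):
            raise ValueError("lasso.lambda_strategy must be 'inner_cv' or 'fixed'")
        if self.lambda_strategy == "fixed" and (self.fixed_lambda is None or self.fixed_lambda < 0):
            raise ValueError("lasso.fixed_lambda must be a non-negative number for strategy 'fixed'")
        if self.tol <= 0 or self.max_iter < 1 or self.n_lambda < 2:
            raise ValueError("lasso.tol/max_iter/n_lambda out of range")
        if not 0.0 < self.ratio_min < 1.0:
            raise ValueError("lasso.ratio_min must be in (0, 1)")
        if self.inner_folds < 2:
            raise ValueError("lasso.inner_folds must be at least 2")


@dataclass(frozen=True)
class CvConfig:
    ci_method: str = "normal"  # or "bootstrap"
    bootstrap_reps: int = 2000

    def __post_init__(self) -> None:
        if self.ci_method not in ("normal", "bootstrap"):
            raise ValueError("cv.ci_method must be 'normal' or 'bootstrap'")
        if self.bootstrap_reps < 100:
            raise ValueError("cv.bootstrap_reps must be at least 100")


@dataclass(frozen=True)
class PipelineConfig:
    roi: RoiConfig = field(default_factory=RoiConfig)
    lasso: LassoConfig = field(default_factory=LassoConfig)
    cv: CvConfig = field(default_factory=CvConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _build(cls, data: dict, where: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML/JSON config file and apply flat CLI overrides.

    ``overrides`` maps dotted keys (e.g. ``"lasso.fixed_lambda"``) to values
    and wins over the file; both win over defaults.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        section, _, name = key.partition(".")
        if name:
            data.setdefault(section, {})[name] = value
        else:
            data[section] = value
    unknown = set(data) - {"roi", "lasso", "cv", "seed"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    return PipelineConfig(
        roi=_build(RoiConfig, data.get("roi", {}), "roi"),
        lasso=_build(LassoConfig, data.get("lasso", {}), "lasso"),
        cv=_build(CvConfig, data.get("cv", {}), "cv"),
        seed=int(data.get("seed", 0)),
    )
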