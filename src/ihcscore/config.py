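"""Run configuration and reproducibility fingerprinting.

Every command serializes its effective configuration into a JSON sidecar
next to its outputs, so a result can always be traced back to the exact
stain model, grayscale weights and thresholds that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cohort import DEFAULT_ALPHA, DEFAULT_EXPRESSION_THRESHOLD
from .errors import InvalidParameterError
from .scoring import DEFAULT_GRAYSCALE_WEIGHTS

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Effective pipeline configuration, serialized with every output."""

    stain_preset: str = "hdab"
    grayscale_weights: tuple[float, float, float] = DEFAULT_GRAYSCALE_WEIGHTS
    eps: float = 1.0
    i0: float = 255.0
    expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    equal_var: bool = True
    master_seed: int = 42

    def __post_init__(self) -> None:
        if self.eps <= 0 or self.i0 <= 0:
            raise InvalidParameterError("eps and i0 must be positive")
        if not (0 < self.alpha < 1):
            raise InvalidParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        object.__setattr__(self, "grayscale_weights", tuple(float(w) for w in self.grayscale_weights))

    def to_dict(self) -> dict:
        return asdict(self)

    def fingerprint(self) -> str:
        """Stable short hash of the canonical JSON encoding."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def write_sidecar(self, path: str | Path, extra: dict | None = None) -> None:
        doc = {"config": self.to_dict(), "fingerprint": self.fingerprint()}
        if extra:
            doc.update(extra)
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise InvalidParameterError(f"{path}: config file must hold a mapping")
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidParameterError(f"{path}: unknown config keys {sorted(unknown)}")
        doc.update(overrides)
        if "grayscale_weights" in doc:
            doc["grayscale_weights"] = tuple(doc["grayscale_weights"])
        return cls(**doc)
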