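"""Run configuration: defaults, validation, YAML loading.

Every tunable of the pipeline lives here with its documented range.
Defaults follow the method's published operating point: restart balance
``alpha = 0.5``, module-size exponent ``beta = 1``, GO-term evaluation
window 10..200 annotated proteins.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    alpha: float = 0.5            # propagation vs restart balance, [0, 1)
    beta: float = 1.0             # module fitness exponent, > 0
    tol: float = 1e-6             # L1 convergence threshold, > 0
    max_iter: int = 1000          # propagation iteration cap, >= 1
    sparsify_epsilon: float = 1e-4  # per-row PN threshold, [0, 1]
    min_term: int = 10            # GO filter lower bound (inclusive)
    max_term: int = 200           # GO filter upper bound (inclusive)
    protocol: str = "loocv"       # {"loocv", "tenfold"}
    repeats: int = 100            # ten-fold repetition count
    n_folds: int = 10
    sequential_module: bool = True  # sequential vs static neighbour pruning
    co_domain_requires_ppi: bool = False  # restrict co-domain edges to PIN pairs
    include_genetic: bool = True  # keep BioGRID genetic interactions
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0.0 <= self.sparsify_epsilon <= 1.0):
            raise ValueError("sparsify_epsilon must be in [0, 1]")
        if self.min_term > self.max_term:
            raise ValueError("min_term must not exceed max_term")
        if self.protocol not in ("loocv", "tenfold"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.repeats < 1 or self.n_folds < 2:
            raise ValueError("repeats >= 1 and n_folds >= 2 required")

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config file (if given) and apply keyword overrides.

    Unknown keys are rejected with a field-level message.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
    return RunConfig(**data)
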