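"""Run configuration: every tunable of the inference in one serializable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import yaml

from .rearrangement import PriorConfig


@dataclass
class RunConfig:
    """Settings for one inference run.

    mu grid: log-spaced discretization of the overall mutation rate
    (substitutions/site on the unit-mean-branch-length tree scale).
    cdr3_multiplier: CDR3 columns evolve at this multiple of the flank rate.
    gap_penalty: per-site indel probability used for alignment gap scores.
    prune_threshold: hypotheses more than this many nats below the modal
    hypothesis are dropped before position posteriors.
    """

    chain: str = "heavy"
    mu_lo: float = 0.001
    mu_hi: float = 0.5
    mu_k: int = 25
    n_max: int = 30
    d_trim_max: int = 10
    cdr3_multiplier: float = 2.0
    gap_penalty: float = 0.01
    prune_threshold: float = 20.0
    max_hypotheses: int = 2000
    max_iter: int = 20
    branch_tolerance: float = 1e-4
    free_end_gaps: bool = True
    flat_prior: bool = False
    seed: Optional[int] = None
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.chain not in ("heavy", "light"):
            raise ValueError(f"chain must be 'heavy' or 'light', got {self.chain!r}")
        for name in ("mu_lo", "mu_hi", "cdr3_multiplier", "gap_penalty",
                     "prune_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu_hi <= self.mu_lo or self.mu_k < 1:
            raise ValueError("mu grid must have mu_lo < mu_hi and k >= 1")
        if self.n_max < 0 or self.max_iter < 1:
            raise ValueError("n_max must be >= 0 and max_iter >= 1")

    def prior_config(self) -> PriorConfig:
        return PriorConfig(n_max=self.n_max, d_trim_max=self.d_trim_max)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
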