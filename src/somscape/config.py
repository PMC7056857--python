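"""Run configuration: every knob of the five-stage pipeline in one place.

A config serialises losslessly to JSON; unknown keys are rejected on
load so stale or misspelled fields fail fast.  All randomness of a run
flows from the single ``seed``, fanned out to the stages through a
deterministic counter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    # stage 1: lattice + training
    shape: str = "trefoil"
    scale: int = 4
    rough_iters: int = 10
    finetune_iters: int = 20
    init: str = "linear"
    standardize: bool = False
    # stage 2: overlay
    smoothing_sigma: float | None = None  # None -> final training sigma
    # stage 3: clustering
    plateau_tol: float = 1e-12
    k_max: int | None = None
    # stage 4: summary
    summary_statistic: str = "mean"
    # stage 5: enrichment
    tails: str = "two"
    alpha: float = 0.05
    # inputs: either file paths ...
    matrix_path: str | None = None
    overlay_path: str | None = None
    gmt_path: str | None = None
    # ... or a synthetic run (used when matrix_path is None)
    synthetic: dict = field(
        default_factory=lambda: {
            "n_genes": 600,
            "n_measures": 4,
            "k_groups": 3,
            "noise_sd": 1.0,
            "status_probs": [0.8, 0.1, 0.1],
            "planted_sets": [[1, 0.8, 0.05]],
            "n_decoys": 9,
        }
    )
    seed: int = 0
    render: bool = False

    def stage_seed(self, stage: int) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        return (self.seed * 100003 + stage * 7919 + 17) % (2**31)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
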