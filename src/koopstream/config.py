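"""Pipeline configuration with the canonical hyperparameters as defaults."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .datatypes import KoopstreamError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Hyperparameters of the end-to-end feature-extraction run.

    Defaults are the canonical full-scale values: 3-s standardization,
    10-ms smoothing, 200 Hz working rate, s=799 delays with decay
    alpha=0.001, diffusion-map bandwidth from kmin=12 neighbors with a
    knn=192 sparsified kernel, and a 1.67 Hz triplet fundamental.
    """

    # preprocessing
    std_window_s: float = 3.0
    smooth_ms: float = 10.0
    target_rate: float = 200.0
    # delay embedding
    s: int = 799
    alpha: float = 0.001
    # diffusion maps
    kmin: int = 12
    knn: int = 192
    n_eigs: int = 150
    squared_bandwidth: bool = True
    theiler: int | None = None   # temporal kNN exclusion; None -> s
    # dictionary selection
    tol_f: float = 0.2
    theta: float = 0.3
    run_length: int = 3
    # branches
    f_triplet: float = 1.0 / 0.6
    tol_real: float = 0.05
    # prediction
    rt: float = 0.65
    # statistics
    n_perm: int = 10_000
    n_bins: int = 25
    stats_seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 1 or self.kmin < 1 or self.knn <= self.kmin:
            raise KoopstreamError("invalid embedding/diffusion parameters")
        if self.target_rate <= 0 or self.f_triplet <= 0:
            raise KoopstreamError("rates must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text_or_path) -> "PipelineConfig":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls(**json.loads(text))
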