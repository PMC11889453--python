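"""Run configuration shared by every pipeline stage."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    """Tunable parameters for a full pseudotime run.

    Defaults correspond to the method's reference settings: 10 000 highly
    variable genes, a rank-20 latent semantic index, mini-batches of 20
    cells, 10% origin/middle/end state fractions, 0.2/0.8 orientation
    cut-offs, an epsilon of 0.1 on the cluster-time edge filter and a
    0.01 confidence floor on the transition threshold.
    """

    hvg_count: int = 10_000
    lsi_rank: int = 20
    batch_size: int = 20
    origin_frac: float = 0.10
    end_frac: float = 0.10
    middle_frac: float = 0.10
    orient_low: float = 0.2
    orient_high: float = 0.8
    epsilon: float = 0.1
    confidence_floor: float = 0.01
    seed: int = 0

    # normalization
    target_sum: float | None = None
    log1p: bool = True
    min_counts: int = 1000
    max_mito_frac: float = 0.2

    # neighbor graph / clustering
    n_neighbors: int = 15
    resolution: float = 1.0
    dpt_components: int = 10

    # regressor
    epochs: int = 150
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    patience: int = 20

    # orientation: override the automatic transcriptional-diversity rule
    flip_orientation: bool = False
    # diversity score: "gene_count" (genes detected per cell) or
    # "mean_expression" (mean normalized expression per cell)
    diversity_score: str = "gene_count"

    def __post_init__(self) -> None:
        for name in ("origin_frac", "end_frac", "middle_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 0.5:
                raise ValueError(f"{name} must lie in (0, 0.5); got {v}")
        if self.lsi_rank < 1:
            raise ValueError(f"lsi_rank must be >= 1; got {self.lsi_rank}")
        if not self.orient_low < self.orient_high:
            raise ValueError(
                "orient_low must be smaller than orient_high; got "
                f"{self.orient_low} >= {self.orient_high}"
            )
        if self.diversity_score not in ("gene_count", "mean_expression"):
            raise ValueError(f"unknown diversity_score {self.diversity_score!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
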