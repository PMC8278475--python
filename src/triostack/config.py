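"""Pipeline configuration: one YAML-loadable dataclass, one seed.

Defaults reproduce the reference settings: 10 outer folds, 5 inner subsets,
k = 0.5 discretization, feature-count sweep n = 5..30 with first-peak
selection, |log2FC| gates 3 (expression) / 0.5 (methylated genes), FDR 0.05,
and the standard base-learner grids.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .containers import METHYLATED_GENE, NCRNA, PROTEIN_CODING


@dataclass
class PipelineConfig:
    # input paths (matrix TSVs, manifest, optional label override)
    pc_path: str | None = None
    nc_path: str | None = None
    meth_path: str | None = None
    manifest_path: str | None = None
    labels_path: str | None = None
    output_dir: str = "triostack_out"

    seed: int = 0
    n_outer: int = 10
    n_inner: int = 5
    n_features: int | None = None          # fixed n; None -> sweep n_range
    n_range: tuple[int, int] = (5, 30)

    log2fc_expression: float = 3.0
    log2fc_methylation: float = 0.5
    fdr: float = 0.05
    pseudocount: float = 1.0
    test: str = "welch_t"                  # or "wilcoxon"
    pooling: str = "by_block"              # BH pooling, or "global"
    k: float = 0.5                         # discretization threshold parameter

    use_pc: bool = True
    use_nc: bool = True
    use_meth: bool = True
    use_csafs: bool = True
    normalization: str = "quantile"        # or "none"
    stratify: bool = False
    threshold: float = 0.5                 # decision threshold on meta probability

    meta_grid: tuple[int, ...] = (100, 200, 300)

    def validate(self) -> None:
        if self.n_outer < 2 or self.n_inner < 2:
            raise ValueError("n_outer and n_inner must be >= 2")
        if self.n_features is not None and self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not (self.use_pc or self.use_nc or self.use_meth):
            raise ValueError("at least one data block must be enabled")
        if self.test not in ("welch_t", "wilcoxon"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.normalization not in ("quantile", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.k <= 0:
            raise ValueError("k must be positive")

    @property
    def use_blocks(self) -> tuple[str, ...]:
        blocks = []
        if self.use_pc:
            blocks.append("pc")
        if self.use_nc:
            blocks.append("nc")
        if self.use_meth:
            blocks.append("meth")
        return tuple(blocks)

    @property
    def log2fc_thresholds(self) -> dict[str, float]:
        return {
            PROTEIN_CODING: self.log2fc_expression,
            NCRNA: self.log2fc_expression,
            METHYLATED_GENE: self.log2fc_methylation,
            "cpg_probe": self.log2fc_methylation,
        }

    def pipeline_kwargs(self) -> dict:
        """Extra DiagnosisPipeline parameters derived from this config."""
        return {
            "log2fc_thresholds": self.log2fc_thresholds,
            "fdr": self.fdr,
            "pseudocount": self.pseudocount,
            "test": self.test,
            "pooling": self.pooling,
            "k": self.k,
            "meta_grid": tuple(self.meta_grid),
            "threshold": self.threshold,
        }

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if isinstance(cfg.n_range, list):
            cfg.n_range = tuple(cfg.n_range)
        if isinstance(cfg.meta_grid, list):
            cfg.meta_grid = tuple(cfg.meta_grid)
        return cfg


__all__ = ["PipelineConfig"]
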