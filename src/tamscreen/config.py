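"""Pipeline configuration: defaults, YAML loading, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one place.

    Defaults follow the study conventions where stated (20,000 cell-line /
    5,000 tumor-type permutations, |log2FC| >= 1 at BH p <= 0.05, GSEA
    p_adj <= 0.25) and documented package choices elsewhere (LLoQ exclusion
    above 40% censoring, LLoQ/2 imputation, pooled z-score datasets).
    """

    lloq_exclusion_fraction: float = 0.40
    censored_imputation: str = "half_lloq"  # half_lloq | lloq | drop
    score_pooling: str = "pooled"  # pooled | per_donor
    quartile_size_rule: str = "ceil_n_over_4"
    de_lfc_min: float = 1.0
    de_alpha: float = 0.05
    gsea_weight_exponent: float = 1.0
    gsea_n_permutations: int = 1000
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    gsea_alpha: float = 0.25
    perm_n_cell_line: int = 20_000
    perm_n_tumor_type: int = 5_000
    fdr_method: str = "bh"  # bh | storey
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lloq_exclusion_fraction", "de_alpha", "gsea_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("gsea_n_permutations", "perm_n_cell_line", "perm_n_tumor_type"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.censored_imputation not in ("half_lloq", "lloq", "drop"):
            raise ConfigError(f"unknown censored_imputation {self.censored_imputation!r}")
        if self.score_pooling not in ("pooled", "per_donor"):
            raise ConfigError(f"unknown score_pooling {self.score_pooling!r}")
        if self.fdr_method not in ("bh", "storey"):
            raise ConfigError(f"unknown fdr_method {self.fdr_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        bad = sorted(set(data) - known)
        if bad:
            raise ConfigError(f"unknown config key(s): {', '.join(bad)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
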