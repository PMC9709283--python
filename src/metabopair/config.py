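"""Pipeline configuration with the study's default thresholds.

Defaults follow the published workflow: QC coefficient of variation < 30%,
zero-fraction <= 60%, |log2FC| > 1 with BH-adjusted p < 0.05 in the volcano
stage, 7-fold cross-validation, a 1,000-iteration permutation test, and a
selection cascade of the top 30 VIP-ranked variables with VIP > 1, a
jack-knife CI excluding zero and two-sided FC > 1.2; annotation within
+/-10 ppm for M+H, M+Na and M+H-H2O adducts.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml


@dataclass
class PipelineConfig:
    # quality assurance (percent thresholds)
    cv_max_pct: float = 30.0
    zero_max_pct: float = 60.0
    # volcano pre-selection
    abs_log2fc_min: float = 1.0
    alpha: float = 0.05
    shapiro_alpha: float = 0.05
    use_adjusted_p: bool = True
    zero_impute: str = "half_min"  # or "unit_offset"
    # normalization
    loess_span: float = 0.75
    apply_medfc: bool = True
    apply_loess: bool = True
    # multivariate
    scaling: str = "uv"  # uv | pareto | center_only
    n_folds: int = 7
    n_permutations: int = 1000
    max_orthogonal: int = 3
    vip_mode: str = "total"  # total | predictive
    q2_threshold: float = 0.5
    # selection cascade
    top_n: int = 30
    vip_min: float = 1.0
    fc_min: float = 1.2
    # annotation
    ppm_tolerance: float = 10.0
    adducts: Sequence[str] = field(default_factory=lambda: ("M+H", "M+Na", "M+H-H2O"))
    # misc
    seed: int = 0
    coerce_bad_cells: bool = False

    def __post_init__(self) -> None:
        positive = {
            "cv_max_pct": self.cv_max_pct,
            "zero_max_pct": self.zero_max_pct,
            "abs_log2fc_min": self.abs_log2fc_min,
            "alpha": self.alpha,
            "loess_span": self.loess_span,
            "n_folds": self.n_folds,
            "n_permutations": self.n_permutations,
            "top_n": self.top_n,
            "vip_min": self.vip_min,
            "fc_min": self.fc_min,
            "ppm_tolerance": self.ppm_tolerance,
        }
        for name, val in positive.items():
            if not (val > 0 and val == val):
                raise ValueError(f"config: {name} must be finite and positive, got {val}")
        if self.scaling not in ("uv", "pareto", "center_only"):
            raise ValueError(f"config: unknown scaling {self.scaling!r}")
        if self.vip_mode not in ("total", "predictive"):
            raise ValueError(f"config: unknown vip_mode {self.vip_mode!r}")
        if self.zero_impute not in ("half_min", "unit_offset"):
            raise ValueError(f"config: unknown zero_impute {self.zero_impute!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["adducts"] = list(d["adducts"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)
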