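"""Run configuration: YAML in, validated dataclass out."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; round-trips through YAML."""

    proteins: str
    mrna: str
    mirna: str
    gene_map: str
    outdir: str
    clinical: str | None = None
    screen: str | None = None
    targets: dict[str, str] = field(default_factory=dict)

    delta0: float = 0.1
    target_fdr: float = 0.01
    prescreen_alpha: float = 0.01
    cv_folds: int = 10
    cv_seed: int = 0
    penalize_gamma: bool = False
    lambda_rule: str = "min"
    row_k: int | None = None       # None -> gap-statistic suggestion
    col_k: int | None = None
    patient_k: int = 2
    edge_threshold: float = 0.15
    screen_threshold: float = 1.96
    min_algorithms: int = 2

    def __post_init__(self) -> None:
        if not self.delta0 > 0:
            raise ValueError("delta0 must be > 0")
        if not 0 <= self.target_fdr < 1:
            raise ValueError("target_fdr must be in [0, 1)")
        if not 0 < self.prescreen_alpha <= 1:
            raise ValueError("prescreen_alpha must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")
        if self.edge_threshold < 0:
            raise ValueError("edge_threshold must be >= 0")
        if self.screen_threshold < 0:
            raise ValueError("screen_threshold must be >= 0")
        if self.patient_k < 2:
            raise ValueError("patient_k must be >= 2")
        if self.min_algorithms < 1:
            raise ValueError("min_algorithms must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**raw)
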