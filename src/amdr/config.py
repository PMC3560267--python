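"""Run configuration with documented defaults and YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All knobs of an analysis run.

    Defaults: pairwise interactions (k=2), B=1000 phenotype permutations,
    B_j=200 jackknife draws keeping 90% of subjects, AUC-maximizing
    significance threshold, FDR rule for the network, odds ratio as the
    primary statistic, seed 0.
    """

    input: str | None = None
    dialect: str = "mdr-flat"
    class_column: str = "Class"
    k: int = 2
    B: int = 1000
    B_j: int = 200
    fraction: float = 0.9
    alpha_mode: str = "auc-max"  # or a fixed numeric threshold as string
    significance_rule: str = "fdr"
    statistic: str = "OR"
    seed: int = 0
    outdir: str = "amdr-out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
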