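"""Pipeline configuration with the study defaults.

Defaults: BLAST e-value cutoff 1e-10, |Spearman rho| cutoff 0.8, random-walk
damping lambda = 0.01, neighborhood radii k in {1, 2}, 10-fold
cross-validation.  The shortest-path length-agreement tolerance epsilon and
the optional random-walk weight gate are reconstruction choices exposed here.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    evalue_cutoff: float = 1e-10
    correlation_cutoff: float = 0.8
    lam: float = 0.01
    hops: tuple[int, ...] = (1, 2)
    sp_epsilon_unit: float = 0.0
    sp_epsilon_correlation: float = 0.05
    rw_weight_gate: float | None = None
    folds: int = 10
    hits_max_iter: int = 1000
    hits_tol: float = 1e-8

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hops"] = list(self.hops)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "hops" in d:
            d = {**d, "hops": tuple(d["hops"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)
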