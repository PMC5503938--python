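"""Run configuration: every threshold of the pipeline in one place.

Two named policy modes encode the two alignment regimes so they cannot be
mixed silently: ``cellline`` (16-28 nt perfect matches, the two-sample
differential screen) and ``sra_survey`` (>=16 nt unbounded, the cohort
survey). Every report embeds the resolved configuration for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

from .exact_matcher import MatchPolicy


@dataclass
class RunConfig:
    mode: str = "cellline"  # 'cellline' or 'sra_survey'
    expression_threshold_cpm: float = 250.0
    min_fold: float = 5.0
    tiers: tuple[float, ...] = (5.0, 7.5, 75.0)
    preference_cutoff: float = 5.5
    fixed_threshold: float = 0.90
    min_hits: int = 10
    delta5: int = 0
    delta3: int = 3
    pseudocount: float = 0.1
    cpm_denominator: str = "raw"  # 'raw' or 'filtered'
    strands: str = "sense"
    multi_reference: str = "all"
    min_read_len: int = 17
    max_read_len: int = 35
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cellline", "sra_survey"):
            raise ValueError("mode must be 'cellline' or 'sra_survey'")
        if self.cpm_denominator not in ("raw", "filtered"):
            raise ValueError("cpm_denominator must be 'raw' or 'filtered'")
        for name in ("expression_threshold_cpm", "min_fold",
                     "preference_cutoff", "fixed_threshold", "pseudocount"):
            if getattr(self, name) <= 0 and name != "pseudocount":
                raise ValueError(f"{name} must be positive")

    @property
    def match_policy(self) -> MatchPolicy:
        max_len = 28 if self.mode == "cellline" else None
        return MatchPolicy(min_len=16, max_len=max_len, strands=self.strands,
                           multi_reference=self.multi_reference)

    def cpm_total(self, library) -> int:
        """CPM denominator per configuration: the raw pre-filter read total
        (default) or the post-length-filter count."""
        if self.cpm_denominator == "raw":
            return library.total_reads
        return len(library.reads)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tiers"] = list(self.tiers)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "tiers" in data:
            data["tiers"] = tuple(data["tiers"])
        return cls(**data)

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


__all__ = ["RunConfig"]
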