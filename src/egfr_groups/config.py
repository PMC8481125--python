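"""Pipeline configuration: a strict, fully-serialisable schema.

Unknown keys are rejected so a typo in a config file fails loudly, and
the resolved configuration is written alongside every output bundle for
provenance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class CartSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_split: int = 8
    cp: float = 0.01
    min_bucket: Optional[int] = None


class ScreenSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sigma: float = 0.2
    sigma_mutation: float = 0.1
    well_sigma: float = 0.02
    n_replicates: int = 3
    wt_ic50_nm: float = 100.0
    raw_wells: bool = False  # emit per-well signals and fit curves


class CohortSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    # arm key "group|generation" -> median months
    medians: dict[str, float] = Field(
        default_factory=lambda: {
            "PACC|2nd": 21.7, "PACC|1st": 10.0, "PACC|3rd": 4.1,
        }
    )
    n_per_arm: int = 50
    censoring: float = 0.2
    endpoint: str = "TTF"


class PipelineConfig(BaseModel):
    """Configuration for the end-to-end synthetic pipeline run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "pipeline_out"
    log_base: float = 10.0
    linkage: str = "complete"
    panel_counts: dict[str, int] = Field(
        default_factory=lambda: {
            "classical-like": 6, "T790M-like-3S": 6, "Ex20ins-L": 6, "PACC": 6,
        }
    )
    region_map: Optional[dict] = None  # RegionMap overrides
    cart: CartSettings = Field(default_factory=CartSettings)
    screen: ScreenSettings = Field(default_factory=ScreenSettings)
    cohort: CohortSettings = Field(default_factory=CohortSettings)
    # optional external inputs (used instead of simulation when given)
    mutations_file: Optional[str] = None
    screen_file: Optional[str] = None
    cohort_file: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
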