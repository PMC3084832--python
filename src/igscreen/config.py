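"""Run configuration: one human-editable file driving the whole pipeline.

Defaults match the study's stated values (0.75 reactive threshold, 95 % CIs,
500 cells per culture, 125-2,500-cell dilution doses).  CLI flags override
config values; every source of randomness flows from the single ``seed``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator


class QCLimits(BaseModel):
    cv_ceiling: float = 0.20
    min_pos_over_neg: float = 2.0
    min_control_wells: int = 3


class RunConfig(BaseModel):
    """Pipeline configuration; see module docstring."""

    out_dir: str = "igscreen_out"
    seed: int = 0
    threshold: float = 0.75                 # reactive call: relative absorbance >
    ci_level: float = 0.95
    estimator: str = "mle"                  # lda method: mle | crossing37
    ci_method: str = "profile"              # profile | bootstrap
    cells_per_culture: int = 500
    cultures_per_patient: int = 90
    dilution_doses: tuple[int, ...] = (125, 250, 500, 1000, 2500)
    wells_per_dose: int = 24
    qc: QCLimits = Field(default_factory=QCLimits)

    @model_validator(mode="after")
    def _check(self):
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.estimator not in ("mle", "crossing37"):
            raise ValueError("estimator must be 'mle' or 'crossing37'")
        return self

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**(data or {}))

    def save(self, path) -> None:
        path = Path(path)
        data = self.model_dump(mode="json")
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))

    def config_hash(self) -> str:
        """Stable digest of the configuration, recorded in every manifest."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
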