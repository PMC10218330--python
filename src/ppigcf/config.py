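"""Pipeline configuration: one dataclass, loadable from YAML.

Every tunable named by the filter stages lives here with its default, so a
run is reproducible from the config snapshot embedded in its report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .corr_filter import NEGATIVE_PCC_POLICIES
from .errors import ConfigInvalidError
from .grouping import DEFAULT_TARGET_TERMS


@dataclass
class PipelineConfig:
    #: anchor GO terms used for grouping
    target_terms: list[str] = field(
        default_factory=lambda: list(DEFAULT_TARGET_TERMS)
    )
    #: groups smaller than this cannot form edges and are skipped
    group_min_size: int = 2
    #: interaction-edge threshold on the similarity-weighted correlation
    tau_ppi: float = 0.5
    #: negative-correlation removal rule: mean | any | majority
    negative_pcc_policy: str = "mean"
    #: NSCC share gate; "auto" = 1/(k-1) for a k-gene group
    theta_R: object = "auto"
    #: likelihood-score gate
    theta_L: float = 0.5
    #: semantic-similarity gate
    theta_S: float = 0.5
    #: IC normalisation; -1 makes IC the binary entropy in [0, 1]
    lambda_: float = -1.0
    #: IC selection threshold; "auto" = mean of the GOA table
    delta: object = "auto"
    #: optional path to a 6x4 GOA threshold TSV replacing the packaged table
    goa_table: str | None = None
    #: ic | cet_times_ic
    score_mode: str = "ic"
    #: missing-value handling on load: None (reject) or "median"
    impute: str | None = None
    #: expression shift applied when the grand mean is exactly 0
    sem_offset: float | None = None
    #: flows to simulation and CV splits; the filter itself is deterministic
    seed: int = 42

    def validate(self) -> None:
        if not self.target_terms:
            raise ConfigInvalidError("target_terms must be non-empty")
        if len(set(self.target_terms)) != len(self.target_terms):
            raise ConfigInvalidError("target_terms must be distinct")
        if not 0.0 < self.tau_ppi <= 1.0:
            raise ConfigInvalidError("tau_ppi must lie in (0, 1]")
        if self.negative_pcc_policy not in NEGATIVE_PCC_POLICIES:
            raise ConfigInvalidError(
                f"negative_pcc_policy must be one of {NEGATIVE_PCC_POLICIES}"
            )
        for name in ("theta_L", "theta_S"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigInvalidError(f"{name} must lie in [0, 1]")
        if self.theta_R != "auto" and not 0.0 <= float(self.theta_R) <= 1.0:
            raise ConfigInvalidError("theta_R must be 'auto' or in [0, 1]")
        if self.lambda_ == 0:
            raise ConfigInvalidError("lambda must be nonzero")
        if self.delta != "auto":
            float(self.delta)
        if self.score_mode not in ("ic", "cet_times_ic"):
            raise ConfigInvalidError("score_mode must be ic | cet_times_ic")
        if self.impute not in (None, "median"):
            raise ConfigInvalidError("impute must be null or 'median'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigInvalidError(f"{path}: not a mapping")
        raw.pop("version", None)
        if "lambda" in raw:
            raw["lambda_"] = raw.pop("lambda")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigInvalidError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lambda"] = d.pop("lambda_")
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
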