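"""Pipeline configuration.

Every threshold the screen uses lives here rather than in code:
the 5-worm minimum per well, the 1.5-/2.0-fold repeatability rules,
the 5% candidate tails, the 0.05 significance level, the 20% progeny
rule for sterile clones and the control separation bounds. Defaults
are the screen's operating values; everything can be overridden from a
YAML file or CLI flags.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ConfigError", "PipelineConfig"]


class ConfigError(ValueError):
    """An invalid or unknown configuration value."""


@dataclass
class PipelineConfig:
    """Thresholds and switches for the whole pipeline.

    Normalization
        min_worms: a well needs at least this many objects to carry a
            signal (the screen seeds 5–8 L1s per well).
        mad_scaled: divide by 1.4826·MAD instead of the bare MAD.
        min_experimental_wells: minimum usable experimental wells per
            plate before normalization is meaningful.
    QC
        sterile_fraction: wells below this fraction of the plate-mean
            progeny count are sterile/lethal (strict inequality).
        repeat_fold_primary / repeat_fold_secondary: between-repeat fold
            change above which (strictly) a clone is low-repeatability
            in the genome-wide and validation rounds respectively.
        exclude_low_repeat_primary: in the genome-wide round the
            repeatability rule governs plate redos (flagged clones are
            reported and drive the plate verdict but stay candidates,
            since in practice low-repeatability plates are re-measured,
            not discarded); set True to instead drop flagged clones
            from candidacy.
        control_up_min / control_down_max: minimum up-control and
            maximum down-control fold versus the empty-vector baseline.
        redo_fraction: a plate is verdicted ``redo`` when more than this
            fraction of its clones are flagged low-repeatability.
    Hit calling
        tail_fraction: total tail mass of the mean-rZ distribution taken
            as candidates (split evenly between the two tails).
        alpha: significance level of the one-tailed validation t-test
            and of the counterscreen exclusion.
        equal_var: pooled-variance t-test instead of Welch.
        bh_correction: Benjamini–Hochberg adjust the secondary p-values
            (off by default; the screen uses raw p-values).
    Endpoints
        immobile_speed_mm_s: |velocity| below which a frame counts as
            immobile.
    """

    min_worms: int = 5
    mad_scaled: bool = False
    min_experimental_wells: int = 8
    sterile_fraction: float = 0.20
    repeat_fold_primary: float = 1.5
    repeat_fold_secondary: float = 2.0
    control_up_min: float = 2.0
    control_down_max: float = 0.7
    redo_fraction: float = 0.25
    exclude_low_repeat_primary: bool = False
    tail_fraction: float = 0.05
    alpha: float = 0.05
    equal_var: bool = False
    bh_correction: bool = False
    immobile_speed_mm_s: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_worms < 1:
            raise ConfigError("min_worms must be >= 1")
        if not (0.0 < self.sterile_fraction < 1.0):
            raise ConfigError("sterile_fraction must be in (0, 1)")
        if self.repeat_fold_primary < 1.0 or self.repeat_fold_secondary < 1.0:
            raise ConfigError("repeatability fold thresholds must be >= 1")
        if not (0.0 < self.tail_fraction <= 0.5):
            raise ConfigError("tail_fraction must be in (0, 0.5]")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must be in (0, 1)")
        if not (0.0 < self.redo_fraction <= 1.0):
            raise ConfigError("redo_fraction must be in (0, 1]")
        if self.immobile_speed_mm_s < 0.0:
            raise ConfigError("immobile_speed_mm_s must be nonnegative")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(dict(data.get("pipeline", data)))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
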