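"""Analysis configuration: defaults, validation, YAML loading."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class AnalysisConfig:
    """Parameters shared by every analysis stage.

    Attributes
    ----------
    period_T : float
        Rhythm period in hours. All Zeitgeber times and acrophases are
        interpreted modulo this period.
    max_harmonics_K : int
        Number of harmonics in the cosinor regression. With 4 distinct
        timepoints only K=1 is identifiable.
    alpha : float
        Significance level for rhythmicity (on BH q-values) and for the
        baseline-change test.
    fdr_method : str
        Multiple-testing procedure label; only "benjamini-hochberg" is
        implemented.
    phase_shift_threshold : float
        Absolute circular phase difference (hours) separating "same phase"
        from "phase shifted" when both conditions are rhythmic.
    baseline_lfc_threshold : float
        Minimum |log2 fold change| for a baseline up/down call.
    seed : int
        Seed for every stochastic stage.
    """

    period_T: float = 24.0
    max_harmonics_K: int = 1
    alpha: float = 0.05
    fdr_method: str = "benjamini-hochberg"
    phase_shift_threshold: float = 3.0
    baseline_lfc_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.period_T <= 0:
            raise ConfigError(f"period_T must be positive, got {self.period_T}")
        if self.max_harmonics_K < 1:
            raise ConfigError(
                f"max_harmonics_K must be a positive integer, got {self.max_harmonics_K}"
            )
        if not 0.0 < self.phase_shift_threshold <= self.period_T / 2:
            raise ConfigError(
                "phase_shift_threshold must lie in (0, period_T/2], got "
                f"{self.phase_shift_threshold}"
            )
        if self.baseline_lfc_threshold < 0:
            raise ConfigError("baseline_lfc_threshold must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a flat YAML file plus overrides.

    CLI flags are passed as ``overrides`` and take precedence over file
    values; ``None`` overrides are ignored so absent flags fall through.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(AnalysisConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return AnalysisConfig(**values)
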