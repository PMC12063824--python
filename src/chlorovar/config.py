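"""Pipeline configuration.

All thresholds used by the analysis live in :class:`PipelineConfig` so that a
run is fully described by one record: the bloom criterion (a rise of
``bloom_delta`` µg/L within ``bloom_window`` days), the 14-day event merging
and context windows, the significance level for backward elimination, the
number of resampling simulations, and the sensor-QC gap tolerance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError

#: Accepted values for the bloom rise criterion.
RISE_CRITERIA = ("endpoint", "minmax")


@dataclass
class PipelineConfig:
    """Constants controlling every stage of the analysis.

    Parameters
    ----------
    bloom_delta:
        Chlorophyll increase (µg/L) that qualifies as a bloom trigger.
    bloom_window:
        Span (days, inclusive) within which the increase must occur.
    merge_window:
        Events closer than this (days) are combined into one.
    event_context:
        Days of data taken before and after the bloom peak for driver models.
    alpha:
        Significance level for backward elimination.
    n_sims:
        Number of resampling simulations per sampling frequency.
    rng_seed:
        Seed for every stochastic step.
    qc_max_gap:
        Longest tolerated run of missing 15-min points (minutes) within a day
        before the daily average is omitted; the rule is strict (a run must
        *exceed* this to trigger omission).
    collinearity_r:
        Absolute pairwise Pearson correlation at or above which one of two
        candidate predictors is dropped.
    ccf_bound:
        Multiplier on 1/sqrt(n) defining the white-noise band used to decide
        whether a one-day lagged predictor enters the candidate set.
    rise_criterion:
        ``"endpoint"`` compares the first and last day of a candidate pair;
        ``"minmax"`` uses the ordered minimum-to-maximum rise within the span.
    """

    bloom_delta: float = 50.0
    bloom_window: int = 4
    merge_window: int = 14
    event_context: int = 14
    alpha: float = 0.05
    n_sims: int = 1000
    rng_seed: int = 0
    qc_max_gap: int = 60
    collinearity_r: float = 0.7
    ccf_bound: float = 1.96
    rise_criterion: str = "endpoint"

    def __post_init__(self) -> None:
        if self.bloom_window < 1 or self.merge_window < 1 or self.event_context < 1:
            raise ValidationError("all windows must be >= 1 day")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.n_sims < 1:
            raise ValidationError("n_sims must be >= 1")
        if self.qc_max_gap < 0:
            raise ValidationError("qc_max_gap must be >= 0 minutes")
        if self.rise_criterion not in RISE_CRITERIA:
            raise ValidationError(f"rise_criterion must be one of {RISE_CRITERIA}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML/JSON key-value file; keyword overrides win."""
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"config file {path} must map keys to values")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(loaded) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        loaded.update(overrides)
        return cls(**loaded)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)
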