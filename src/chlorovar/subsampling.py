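"""Monitoring-frequency simulation.

A contiguous record of useable daily chlorophyll values (one "year", however
many days it holds) is partitioned into contiguous blocks — quarters (4) or
months (12) — whose lengths differ by at most one day.  Each simulation draws
one day uniformly at random from every block; descriptive statistics (annual
mean, minimum, maximum) of the drawn sets, averaged over simulations, are
compared with the raw record to show what a lower-frequency program would
have reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


def partition_blocks(n_days: int, n_blocks: int) -> list[int]:
    """Lengths of contiguous, temporally ordered blocks.

    Lengths differ by at most one and sum to ``n_days``; the first
    ``n_days mod n_blocks`` blocks carry the extra day.  A 171-day record
    splits into quarters of 43/43/43/42 days and months of three 15s and
    nine 14s.
    """
    if n_blocks < 1:
        raise ValidationError("n_blocks must be >= 1")
    if n_blocks > n_days:
        raise ValidationError(f"cannot split {n_days} days into {n_blocks} blocks")
    base, extra = divmod(n_days, n_blocks)
    return [base + 1 if i < extra else base for i in range(n_blocks)]


@dataclass
class SubsamplingResult:
    """Outcome of a resampling experiment at one sampling frequency."""

    frequency: str
    n_sims: int
    per_sim: pd.DataFrame | None  # columns: mean, min, max (None if from_stats)
    raw_mean: float
    raw_min: float
    raw_max: float
    avg_mean: float
    avg_min: float
    avg_max: float

    @classmethod
    def from_stats(
        cls,
        frequency: str,
        avg_mean: float,
        avg_min: float,
        avg_max: float,
        raw_mean: float,
        raw_min: float,
        raw_max: float,
        n_sims: int = 0,
    ) -> "SubsamplingResult":
        """Build a result record from already-summarized statistics (e.g. a
        published descriptive-statistics table) for report arithmetic."""
        return cls(
            frequency=frequency,
            n_sims=n_sims,
            per_sim=None,
            raw_mean=raw_mean,
            raw_min=raw_min,
            raw_max=raw_max,
            avg_mean=avg_mean,
            avg_min=avg_min,
            avg_max=avg_max,
        )


def simulate_sampling(
    values, n_blocks: int, n_sims: int, seed: int, frequency: str | None = None
) -> SubsamplingResult:
    """Draw one sample per block in each of ``n_sims`` simulations.

    ``values`` must be free of missing entries (it is the useable-day
    record).  Each simulation uses its own RNG substream spawned by counter
    from ``seed``, so per-simulation draws are independent of execution
    order and reproducible.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or len(arr) == 0:
        raise ValidationError("values must be a non-empty 1-d sequence")
    if np.isnan(arr).any():
        raise ValidationError("values must not contain missing entries")
    if n_sims < 1:
        raise ValidationError("n_sims must be >= 1")
    lengths = partition_blocks(len(arr), n_blocks)
    if min(lengths) == 0:
        raise ValidationError("empty block")
    bounds = np.concatenate([[0], np.cumsum(lengths)])

    children = np.random.SeedSequence(seed).spawn(n_sims)
    means = np.empty(n_sims)
    mins = np.empty(n_sims)
    maxs = np.empty(n_sims)
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        idx = np.array(
            [rng.integers(bounds[b], bounds[b + 1]) for b in range(n_blocks)]
        )
        drawn = arr[idx]
        means[s] = drawn.mean()
        mins[s] = drawn.min()
        maxs[s] = drawn.max()

    per_sim = pd.DataFrame({"mean": means, "min": mins, "max": maxs})
    if frequency is None:
        frequency = {4: "quarterly", 12: "monthly"}.get(n_blocks, f"{n_blocks}-block")
    return SubsamplingResult(
        frequency=frequency,
        n_sims=n_sims,
        per_sim=per_sim,
        raw_mean=float(arr.mean()),
        raw_min=float(arr.min()),
        raw_max=float(arr.max()),
        avg_mean=float(means.mean()),
        avg_min=float(mins.mean()),
        avg_max=float(maxs.mean()),
    )


def frequency_report(results: list[SubsamplingResult]) -> pd.DataFrame:
    """Comparison table across sampling frequencies.

    Rows are the averaged descriptive statistics per frequency plus the raw
    record; derived columns quantify what lower-frequency sampling misses:
    ``max_deficit`` (raw max − average simulated max), ``min_excess``
    (average simulated min − raw min) and ``pct_reduction_max``
    (100 · max_deficit / raw max).
    """
    if not results:
        raise ValidationError("no results to report")
    raws = {(r.raw_mean, r.raw_min, r.raw_max) for r in results}
    if len(raws) > 1:
        raise ValidationError("results do not share the same raw record")
    raw_mean, raw_min, raw_max = results[0].raw_mean, results[0].raw_min, results[0].raw_max

    rows = []
    for r in results:
        rows.append(
            {
                "frequency": r.frequency,
                "avg_mean": r.avg_mean,
                "avg_min": r.avg_min,
                "avg_max": r.avg_max,
                "max_deficit": raw_max - r.avg_max,
                "min_excess": r.avg_min - raw_min,
                "pct_reduction_max": 100.0 * (raw_max - r.avg_max) / raw_max,
            }
        )
    rows.append(
        {
            "frequency": "raw",
            "avg_mean": raw_mean,
            "avg_min": raw_min,
            "avg_max": raw_max,
            "max_deficit": 0.0,
            "min_excess": 0.0,
            "pct_reduction_max": 0.0,
        }
    )
    return pd.DataFrame(rows).set_index("frequency")
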