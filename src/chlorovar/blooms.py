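"""Bloom event detection on the daily chlorophyll series.

A bloom trigger is a chlorophyll increase of at least ``delta`` µg/L within a
``window``-day span (endpoints at most ``window - 1`` calendar days apart,
both observed; the comparison is inclusive, so a rise of exactly ``delta``
qualifies).  Triggers may bridge omitted days as long as both endpoints are
observed.  Triggers closer together than the merge window are combined into
one event; day 0 of an event is its maximum-chlorophyll day, and the analysis
window extends up to ``context`` days before and after day 0, trimmed to the
available record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import ValidationError
from .io import DailySeries

Pair = tuple[pd.Timestamp, pd.Timestamp]


@dataclass
class BloomEvent:
    """One detected (possibly merged) bloom event."""

    site: str
    trigger_pairs: list[Pair]
    peak_date: pd.Timestamp
    window_start: pd.Timestamp
    window_end: pd.Timestamp
    n_days: int
    max_chl: float

    @property
    def window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return (self.window_start, self.window_end)


def _chl_series(daily) -> pd.Series:
    if isinstance(daily, DailySeries):
        chl = daily.chlorophyll()
    else:
        chl = pd.Series(daily, dtype=float)
        chl.index = pd.DatetimeIndex(chl.index).normalize()
    return chl.dropna()


def detect_rises(
    daily, delta: float = 50.0, window: int = 4, criterion: str = "endpoint"
) -> list[Pair]:
    """All qualifying trigger pairs on the daily chlorophyll record.

    ``criterion="endpoint"`` returns every ordered pair of observed days
    (t1, t2) with ``1 <= t2 - t1 <= window - 1`` days and
    ``chl(t2) - chl(t1) >= delta``.  ``criterion="minmax"`` instead scans each
    ``window``-day span and reports the span's best ordered min-to-max pair
    when its rise reaches ``delta``.
    """
    chl = _chl_series(daily)
    dates = chl.index
    values = chl.to_numpy()
    max_gap = window - 1
    pairs: list[Pair] = []
    if criterion == "endpoint":
        for i in range(len(dates)):
            for j in range(i + 1, len(dates)):
                span = (dates[j] - dates[i]).days
                if span > max_gap:
                    break
                if values[j] - values[i] >= delta:
                    pairs.append((dates[i], dates[j]))
    elif criterion == "minmax":
        seen = set()
        for i in range(len(dates)):
            lo = dates[i]
            in_span = [k for k in range(i, len(dates)) if (dates[k] - lo).days <= max_gap]
            best, best_pair = -np.inf, None
            for a_pos, a in enumerate(in_span):
                for b in in_span[a_pos + 1 :]:
                    rise = values[b] - values[a]
                    if rise > best:
                        best, best_pair = rise, (dates[a], dates[b])
            if best >= delta and best_pair not in seen:
                seen.add(best_pair)
                pairs.append(best_pair)
    else:
        raise ValidationError(f"unknown rise criterion {criterion!r}")
    return pairs


def _cluster_pairs(pairs: list[Pair], merge_window: int) -> list[list[Pair]]:
    """Single-linkage clustering of trigger pairs by end date."""
    ordered = sorted(pairs, key=lambda p: (p[1], p[0]))
    clusters: list[list[Pair]] = []
    for pair in ordered:
        if clusters and (pair[1] - clusters[-1][-1][1]).days <= merge_window:
            clusters[-1].append(pair)
        else:
            clusters.append([pair])
    return clusters


def _peak_in(chl: pd.Series, start: pd.Timestamp, end: pd.Timestamp) -> pd.Timestamp:
    region = chl.loc[start:end]
    # ties broken by earliest date (idxmax returns the first maximum)
    return region.idxmax()


def merge_events(
    pairs: list[Pair],
    daily,
    merge_window: int = 14,
    context: int = 14,
    site: str | None = None,
) -> list[BloomEvent]:
    """Combine trigger pairs into distinct bloom events.

    Pairs are clustered by single linkage on their end dates with gap
    <= ``merge_window`` days; each cluster's peak (day 0) is the maximum
    chlorophyll day over the cluster span extended by ``context`` days each
    side.  Clusters whose peaks still fall within ``merge_window`` days of
    each other are merged again, so returned events are pairwise separated by
    more than ``merge_window`` days peak-to-peak.
    """
    if not pairs:
        return []
    chl = _chl_series(daily)
    if site is None:
        site = daily.site if isinstance(daily, DailySeries) else "unknown"
    ctx = pd.Timedelta(days=context)
    first_obs, last_obs = chl.index[0], chl.index[-1]

    clusters = _cluster_pairs(pairs, merge_window)
    while True:
        peaks = []
        for cluster in clusters:
            span_start = min(p[0] for p in cluster)
            span_end = max(p[1] for p in cluster)
            peaks.append(_peak_in(chl, span_start - ctx, span_end + ctx))
        merged_any = False
        i = 0
        while i + 1 < len(clusters):
            if abs((peaks[i + 1] - peaks[i]).days) <= merge_window:
                clusters[i] = clusters[i] + clusters.pop(i + 1)
                peaks.pop(i + 1)
                merged_any = True
            else:
                i += 1
        if not merged_any:
            break

    events = []
    for cluster, peak in zip(clusters, peaks):
        w_start = max(peak - ctx, first_obs)
        w_end = min(peak + ctx, last_obs)
        in_window = chl.loc[w_start:w_end]
        events.append(
            BloomEvent(
                site=site,
                trigger_pairs=sorted(cluster),
                peak_date=peak,
                window_start=w_start,
                window_end=w_end,
                n_days=int(in_window.notna().sum()),
                max_chl=float(chl.loc[peak]),
            )
        )
    return events


def detect_blooms(daily, config: PipelineConfig | None = None) -> list[BloomEvent]:
    """Full detector: rises, then merging, using the pipeline configuration."""
    cfg = config or PipelineConfig()
    pairs = detect_rises(
        daily, delta=cfg.bloom_delta, window=cfg.bloom_window, criterion=cfg.rise_criterion
    )
    return merge_events(
        pairs, daily, merge_window=cfg.merge_window, context=cfg.event_context
    )


def events_table(events: list[BloomEvent]) -> pd.DataFrame:
    """Events as a flat table (one row per event)."""
    return pd.DataFrame(
        {
            "site": [e.site for e in events],
            "peak_date": [e.peak_date.date() for e in events],
            "window_start": [e.window_start.date() for e in events],
            "window_end": [e.window_end.date() for e in events],
            "n_days": [e.n_days for e in events],
            "max_chl": [e.max_chl for e in events],
            "n_triggers": [len(e.trigger_pairs) for e in events],
        }
    )
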