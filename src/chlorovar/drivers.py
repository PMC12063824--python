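"""Per-event driver-model selection.

For each bloom event the daily chlorophyll series is paired with candidate
environmental predictors over the ±context-day window: average wind speed,
one-day-lagged average wind speed, maximum sustained wind speed, water
temperature, and rainfall.  The workflow is:

1. build the event frame (complete-case rows, lag columns, zero-variance
   predictors dropped — e.g. rain during a rain-free event);
2. decide with a cross-correlation screen whether the one-day-lagged wind
   term belongs in the candidate set;
3. remove collinear candidates (pairwise |r| at or above the threshold; the
   member less correlated with chlorophyll is dropped);
4. enumerate every additive OLS subset of the surviving candidates on the
   same rows, rank by AICc (small-sample corrected AIC);
5. simplify the AICc-best model by backward elimination until every term is
   significant at alpha.

AICc counts the intercept and the residual variance among the estimated
parameters (k = number of slopes + 2), the convention of the standard
model-selection tooling, so the correction term 2k(k+1)/(n-k-1) is
well-defined for the small event samples (n = 10-25) this targets.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .blooms import BloomEvent
from .config import PipelineConfig
from .errors import ValidationError
from .io import DailySeries, MetSeries

logger = logging.getLogger(__name__)

#: Candidate predictor roles, in deterministic order.
CANDIDATES = ("wind_avg", "wind_avg_lag1", "wind_max", "temperature", "rain")
RESPONSE = "chlorophyll"

_MAX_CANDIDATES = 12


@dataclass
class EventFrame:
    """Response + candidate predictors for one bloom event window."""

    data: pd.DataFrame  # index: date; columns: chlorophyll + candidates
    candidates: list[str]
    dropped: dict[str, str] = field(default_factory=dict)
    analyzable: bool = True
    reason: str | None = None
    event: BloomEvent | None = None

    @property
    def n(self) -> int:
        return len(self.data)


@dataclass
class DriverModelFit:
    """Final additive linear model for one event."""

    terms: tuple[str, ...]
    coefficients: dict[str, float]  # includes "intercept"
    p_values: dict[str, float]
    adj_r2: float
    model_p: float
    aicc: float
    n: int
    significant: bool  # False when elimination removed every term

    def to_row(self) -> dict:
        row: dict = {"n": self.n, "adj_r2": self.adj_r2, "model_p": self.model_p,
                     "aicc": self.aicc, "significant": self.significant}
        for t in self.terms:
            row[f"coef_{t}"] = self.coefficients[t]
            row[f"p_{t}"] = self.p_values[t]
        return row


def build_event_frame(
    event: BloomEvent, daily: DailySeries, met: MetSeries
) -> EventFrame:
    """Assemble the per-event regression frame.

    The event is flagged not-analyzable when meteorology does not cover the
    whole window (including the day before the first window date, needed for
    the one-day lag) — this is the coverage filter that limits which detected
    events can be modeled.  Zero-variance predictors are dropped with a note.
    """
    dates = pd.date_range(event.window_start, event.window_end, freq="D")
    met_needed = pd.date_range(event.window_start - pd.Timedelta(days=1),
                               event.window_end, freq="D")
    met_df = met.data.reindex(met_needed)
    if met_df[["wind_avg", "wind_max", "rain"]].isna().any().any():
        n_missing = int(met_df[["wind_avg", "wind_max", "rain"]].isna().any(axis=1).sum())
        return EventFrame(
            data=pd.DataFrame(),
            candidates=[],
            analyzable=False,
            reason=f"met coverage incomplete over window ({n_missing} days missing)",
            event=event,
        )

    frame = pd.DataFrame(index=dates)
    frame[RESPONSE] = daily.chlorophyll().reindex(dates)
    frame["wind_avg"] = met_df["wind_avg"].reindex(dates)
    frame["wind_avg_lag1"] = met_df["wind_avg"].shift(1).reindex(dates)
    frame["wind_max"] = met_df["wind_max"].reindex(dates)
    frame["temperature"] = daily.data["temperature"].reindex(dates)
    frame["rain"] = met_df["rain"].reindex(dates)

    frame = frame.dropna(axis=0, how="any", subset=[RESPONSE])
    # complete cases fixed once so every candidate model shares n
    frame = frame.dropna(axis=0, how="any")

    candidates, dropped = [], {}
    for cand in CANDIDATES:
        if frame[cand].nunique() <= 1:
            dropped[cand] = "zero variance over the event window"
            logger.info("event %s: %s excluded (%s)", event.peak_date.date(),
                        cand, dropped[cand])
        else:
            candidates.append(cand)
    return EventFrame(data=frame, candidates=candidates, dropped=dropped, event=event)


def ccf_screen(
    chl: pd.Series,
    predictor: pd.Series,
    max_lag: int = 1,
    bound_mult: float = 1.96,
) -> dict:
    """Cross-correlation screen for a one-day-lagged predictor.

    Computes the Pearson correlation between the predictor and chlorophyll at
    lag 0 and at lag 1 (predictor leading).  The lagged variant enters the
    candidate set iff |r(lag 1)| reaches the white-noise band
    ``bound_mult / sqrt(n)``.  Constant inputs yield ``include=False`` with a
    warning.
    """
    if max_lag != 1:
        raise ValidationError("only a one-day lag is screened")
    chl = pd.Series(chl, dtype=float)
    predictor = pd.Series(predictor, dtype=float)
    paired = pd.concat([chl.rename("y"), predictor.rename("x")], axis=1).dropna()
    if len(paired) < 6:
        raise ValidationError("ccf_screen needs at least 6 paired observations")
    if paired["y"].nunique() <= 1 or paired["x"].nunique() <= 1:
        logger.warning("ccf_screen: constant input, lag-1 term excluded")
        return {"r_lag0": np.nan, "r_lag1": np.nan, "n": len(paired),
                "bound": np.nan, "include_lag1": False}

    r0 = float(paired["y"].corr(paired["x"]))
    if isinstance(predictor.index, pd.DatetimeIndex):
        shifted = predictor.shift(1, freq="D")  # lag by calendar day
    else:
        shifted = predictor.shift(1)
    lagged = pd.concat([chl.rename("y"), shifted.rename("x")], axis=1).dropna()
    n1 = len(lagged)
    if n1 < 3 or lagged["x"].nunique() <= 1:
        return {"r_lag0": r0, "r_lag1": np.nan, "n": n1, "bound": np.nan,
                "include_lag1": False}
    r1 = float(lagged["y"].corr(lagged["x"]))
    bound = bound_mult / math.sqrt(n1)
    return {"r_lag0": r0, "r_lag1": r1, "n": n1, "bound": bound,
            "include_lag1": bool(abs(r1) >= bound)}


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected AIC from a least-squares fit.

    ``k`` counts every estimated parameter: slopes + intercept + residual
    variance.  Requires ``n - k - 1 >= 1``; models violating that are skipped
    by the enumerator.  A zero RSS (exact fit) maps to ``-inf`` so exact
    models rank first.
    """
    if n - k - 1 < 1:
        raise ValidationError(f"AICc undefined for n={n}, k={k}")
    if rss <= 0.0:
        return -math.inf
    return n * math.log(rss / n) + 2 * k + (2 * k * (k + 1)) / (n - k - 1)


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    # numerically exact fits snap to zero so ties resolve toward fewer terms
    if rss <= 1e-12 * (float(y @ y) + 1.0):
        return 0.0
    return rss


def enumerate_models(
    frame: EventFrame | pd.DataFrame,
    candidates: list[str] | None = None,
    response: str = RESPONSE,
) -> list[tuple[tuple[str, ...], float]]:
    """Fit every additive subset of the candidates by OLS and rank by AICc.

    All 2^p subsets, including the intercept-only model, are fitted on the
    same complete-case rows.  Subsets for which the AICc correction is
    undefined (n - k - 1 < 1) are skipped.  Returns (terms, aicc) pairs in
    ascending AICc order; ties break toward fewer terms, then lexicographic.
    """
    df = frame.data if isinstance(frame, EventFrame) else frame
    if candidates is None:
        candidates = frame.candidates if isinstance(frame, EventFrame) else [
            c for c in df.columns if c != response
        ]
    p = len(candidates)
    if p > _MAX_CANDIDATES:
        raise ValidationError(f"refusing to enumerate 2^{p} models (p > {_MAX_CANDIDATES})")
    y = df[response].to_numpy(dtype=float)
    n = len(y)
    ones = np.ones((n, 1))
    ranked = []
    for size in range(p + 1):
        for terms in itertools.combinations(candidates, size):
            k = len(terms) + 2
            if n - k - 1 < 1:
                continue
            X = np.hstack([ones] + [df[t].to_numpy(dtype=float)[:, None] for t in terms])
            ranked.append((terms, aicc(_ols_rss(y, X), n, k)))
    ranked.sort(key=lambda item: (item[1], len(item[0]), item[0]))
    return ranked


def prune_collinear(
    frame: EventFrame | pd.DataFrame,
    candidates: list[str] | None = None,
    response: str = RESPONSE,
    r_threshold: float = 0.7,
) -> list[str]:
    """Drop collinear candidates deterministically.

    While any candidate pair has |Pearson r| >= ``r_threshold``, the pair with
    the largest |r| is resolved by dropping the member whose |correlation with
    the response| is smaller (ties: the member later in candidate order).
    """
    df = frame.data if isinstance(frame, EventFrame) else frame
    if candidates is None:
        candidates = list(frame.candidates) if isinstance(frame, EventFrame) else [
            c for c in df.columns if c != response
        ]
    surviving = list(candidates)
    while len(surviving) >= 2:
        corr = df[surviving].corr().abs()
        best_pair, best_r = None, r_threshold
        for i, a in enumerate(surviving):
            for b in surviving[i + 1 :]:
                r = corr.loc[a, b]
                if np.isfinite(r) and r >= best_r:
                    best_pair, best_r = (a, b), r
        if best_pair is None:
            break
        a, b = best_pair
        ra = abs(df[a].corr(df[response]))
        rb = abs(df[b].corr(df[response]))
        drop = b if (np.isnan(rb) or rb <= ra) else a
        logger.info("collinearity: dropping %s (|r| pair=%.3f)", drop, best_r)
        surviving.remove(drop)
    return surviving


def _fit_ols(df: pd.DataFrame, terms: tuple[str, ...], response: str):
    X = sm.add_constant(df[list(terms)], has_constant="add") if terms else pd.DataFrame(
        {"const": np.ones(len(df))}, index=df.index
    )
    return sm.OLS(df[response], X).fit()


def backward_eliminate(
    terms: tuple[str, ...],
    frame: EventFrame | pd.DataFrame,
    alpha: float = 0.05,
    response: str = RESPONSE,
) -> DriverModelFit:
    """Backward elimination from a starting model to an all-significant fit.

    While any term's p-value exceeds alpha, the largest-p term is removed and
    the model refitted.  If every term is eliminated the intercept-only model
    is returned flagged ``significant=False``.
    """
    df = frame.data if isinstance(frame, EventFrame) else frame
    terms = tuple(terms)
    while True:
        fit = _fit_ols(df, terms, response)
        if not terms:
            break
        pvals = fit.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals.loc[worst] > alpha:
            terms = tuple(t for t in terms if t != worst)
        else:
            break

    n = int(fit.nobs)
    k = len(terms) + 2
    crit = aicc(float(fit.ssr), n, k) if n - k - 1 >= 1 else float("nan")
    coefs = {("intercept" if t == "const" else t): float(v)
             for t, v in fit.params.items()}
    pvals_all = {("intercept" if t == "const" else t): float(v)
                 for t, v in fit.pvalues.items()}
    return DriverModelFit(
        terms=terms,
        coefficients=coefs,
        p_values=pvals_all,
        adj_r2=float(fit.rsquared_adj) if terms else 0.0,
        model_p=float(fit.f_pvalue) if terms else float("nan"),
        aicc=crit,
        n=n,
        significant=bool(terms),
    )


def analyze_frame(
    frame: EventFrame, config: PipelineConfig | None = None
) -> DriverModelFit:
    """CCF lag screen, collinearity pruning, AICc enumeration, and backward
    elimination on a prepared event frame."""
    cfg = config or PipelineConfig()
    if not frame.analyzable:
        raise ValidationError(f"event not analyzable: {frame.reason}")
    candidates = list(frame.candidates)
    if "wind_avg_lag1" in candidates:
        screen = ccf_screen(
            frame.data[RESPONSE], frame.data["wind_avg"], bound_mult=cfg.ccf_bound
        )
        if not screen["include_lag1"]:
            candidates.remove("wind_avg_lag1")
            frame.dropped["wind_avg_lag1"] = (
                f"ccf lag-1 |r|={abs(screen['r_lag1']):.3f} below bound"
                if np.isfinite(screen.get("r_lag1", np.nan))
                else "ccf screen: constant input"
            )
    candidates = prune_collinear(
        frame, candidates=candidates, r_threshold=cfg.collinearity_r
    )
    ranked = enumerate_models(frame, candidates=candidates)
    if not ranked:
        raise ValidationError("no candidate model satisfies n - k - 1 >= 1")
    best_terms = ranked[0][0]
    return backward_eliminate(best_terms, frame, alpha=cfg.alpha)


def analyze_event(
    event: BloomEvent,
    daily: DailySeries,
    met: MetSeries,
    config: PipelineConfig | None = None,
) -> tuple[EventFrame, DriverModelFit | None]:
    """End-to-end driver analysis for one bloom event.

    Returns the event frame and the selected model, or ``(frame, None)`` when
    meteorology coverage makes the event not analyzable.
    """
    frame = build_event_frame(event, daily, met)
    if not frame.analyzable:
        return frame, None
    return frame, analyze_frame(frame, config)
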