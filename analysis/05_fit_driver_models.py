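"""Driver-model selection for every detected bloom event.

For each event in results/events.csv (regenerated if absent), assembles the
±14-day chlorophyll + meteorology frame, screens the one-day wind lag by
cross-correlation, prunes collinear candidates, ranks all additive OLS
subsets by AICc and backward-eliminates to an all-significant model — the
machine twin of a per-event coefficient table.  Writes one row per event and
term to results/driver_models.csv.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from chlorovar import BloomEvent, PipelineConfig, analyze_event, read_daily_csv, read_met_csv

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "results" / "fixtures"


def main() -> None:
    if not (ROOT / "results" / "events.csv").exists():
        subprocess.run([sys.executable, str(ROOT / "analysis" / "04_detect_blooms.py")],
                       check=True)
    daily = read_daily_csv(FIXTURES / "daily.csv")
    met = read_met_csv(FIXTURES / "met.csv")
    events = pd.read_csv(ROOT / "results" / "events.csv",
                         parse_dates=["peak_date", "window_start", "window_end"])
    cfg = PipelineConfig()

    rows = []
    for _, ev in events.iterrows():
        event = BloomEvent(site=ev["site"], trigger_pairs=[],
                           peak_date=ev["peak_date"], window_start=ev["window_start"],
                           window_end=ev["window_end"], n_days=int(ev["n_days"]),
                           max_chl=float(ev["max_chl"]))
        frame, fit = analyze_event(event, daily, met, cfg)
        if fit is None:
            rows.append({"peak_date": event.peak_date.date(), "term": None,
                         "note": frame.reason})
            continue
        if not fit.terms:
            rows.append({"peak_date": event.peak_date.date(), "term": "(none)",
                         "n": fit.n, "adj_r2": fit.adj_r2,
                         "note": "no significant model"})
            continue
        for term in fit.terms:
            rows.append({"peak_date": event.peak_date.date(), "term": term,
                         "coefficient": round(fit.coefficients[term], 3),
                         "p_value": round(fit.p_values[term], 4),
                         "adj_r2": round(fit.adj_r2, 3),
                         "model_p": round(fit.model_p, 4),
                         "aicc": round(fit.aicc, 2), "n": fit.n})
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "results" / "driver_models.csv", index=False)

    analyzed = table[table["term"].notna() & (table["term"] != "(none)")]
    wind_terms = analyzed["term"].isin(["wind_avg", "wind_avg_lag1", "wind_max"])
    print(f"driver models for {len(events)} events -> results/driver_models.csv")
    print(f"  events with a significant model: "
          f"{analyzed['peak_date'].nunique()} of {len(events)}")
    print(f"  wind-related terms among selected terms: "
          f"{int(wind_terms.sum())} of {len(analyzed)}")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
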