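"""Short-term disorientation tests on the daily series.

Runs the three day-level tests — basic multinomial against the pooled
yearly proportions, running multinomial against the preceding 15-day
average, and the 15-day running-variance chi-square — and counts
rejection days per significance level against the count expected by
chance, plus a window-length sensitivity table.

Inputs: results/daily.csv (from 02).  Outputs: results/tests_*.csv,
results/test_summaries.json, results/window_sensitivity.csv.
"""

import json
from pathlib import Path

from disorient import (
    DailyPolaritySeries,
    basic_daily_test,
    rejection_summary,
    running_daily_test,
    running_variance_test,
    window_sensitivity,
)

ROOT = Path(__file__).resolve().parents[1]
SEED = 20180101


def main() -> None:
    series = DailyPolaritySeries.from_csv(ROOT / "results" / "daily.csv")
    runs = {
        "basic": basic_daily_test(series, seed=SEED),
        "running": running_daily_test(series, window=15, seed=SEED),
        "variance": running_variance_test(series, window=15),
    }
    summaries = {}
    for name, res in runs.items():
        res.to_csv(ROOT / "results" / f"tests_{name}.csv", index=False)
        summ = rejection_summary(res)
        summaries[name] = summ.to_dict()
        line = ", ".join(
            f"{r} days at alpha={a:g} (expected {e:.1f})"
            for a, r, e in zip(summ.alphas, summ.rejected_days,
                               summ.expected_days))
        print(f"{name:>8}: {line}")
    with open(ROOT / "results" / "test_summaries.json", "w") as fh:
        json.dump(summaries, fh, indent=2)

    sens = window_sensitivity(series, [7, 10, 15, 21, 30], seed=SEED)
    sens.to_csv(ROOT / "results" / "window_sensitivity.csv", index=False)
    at05 = sens[sens["alpha"] == 0.05]
    print("\nwindow sensitivity (rejected days at alpha=0.05):")
    print(at05.pivot(index="window", columns="test",
                     values="rejected_days").to_string())


if __name__ == "__main__":
    main()
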