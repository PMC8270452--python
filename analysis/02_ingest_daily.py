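"""Ingest the simulated post stream into a daily polarity series.

Deduplicates by post id, drops out-of-context posts, bins the rest into
calendar days, and summarises the pooled polarity proportions with
bootstrap confidence intervals — the synthetic analogue of the corpus
retention and polarity-summary stage.

Inputs: scratch/posts.csv (from 01).  Outputs: results/daily.csv,
results/polarity_summary.json.
"""

import json
from datetime import date
from pathlib import Path

from disorient import aggregate_daily, deduplicate, polarity_summary
from disorient.ingest import read_posts_csv

ROOT = Path(__file__).resolve().parents[1]
SEED = 20180101


def main() -> None:
    records = read_posts_csv(ROOT / "scratch" / "posts.csv")
    n_raw = len(records)
    retained = deduplicate(records)
    series = aggregate_daily(retained, date(2018, 1, 1), date(2018, 12, 31))
    series.to_csv(ROOT / "results" / "daily.csv")
    summ = polarity_summary(series, seed=SEED)
    with open(ROOT / "results" / "polarity_summary.json", "w") as fh:
        json.dump(summ.to_dict(), fh, indent=2)
    print(f"read {n_raw} posts; retained {len(retained)} after dedup + "
          f"out-of-context removal ({len(retained) / n_raw:.1%})")
    print(f"pooled proportions: F={summ.p_F:.1%} "
          f"(CI {summ.ci_F[0]:.1%}-{summ.ci_F[1]:.1%}), "
          f"C={summ.p_C:.1%}, U={summ.p_U:.1%}")
    print(f"hesitant share (C+U): {summ.p_hesitant:.1%}")


if __name__ == "__main__":
    main()
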