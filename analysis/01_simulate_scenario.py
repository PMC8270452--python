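"""Generate the year-long demo opinion stream.

Builds the reference scenario — baseline polarity split (0.70, 0.164,
0.136), three dominant volume spikes with short opinion shocks around
them, and a slow logit-quadratic rise-then-fall in the favourable share —
and expands it into individual labelled post records.

Outputs: scratch/posts.csv (the raw post stream, large), and
results/scenario.json + results/truth.json (the generating configuration
and the noiseless truth trajectory).
"""

from pathlib import Path

from disorient import demo_scenario, generate_posts
from disorient.ingest import write_posts_csv

ROOT = Path(__file__).resolve().parents[1]
SEED = 20180101


def main() -> None:
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "scratch").mkdir(exist_ok=True)
    cfg = demo_scenario(SEED)
    cfg.to_json(ROOT / "results" / "scenario.json")
    records, truth = generate_posts(cfg, seed=SEED)
    truth.to_json(ROOT / "results" / "truth.json")
    write_posts_csv(records, ROOT / "scratch" / "posts.csv")
    n_ooc = sum(1 for r in records if r.label == "OOC")
    print(f"wrote {len(records)} posts ({n_ooc} out-of-context, "
          f"{len(records) - n_ooc} polarity-labelled) to scratch/posts.csv")
    print(f"truth: favourable share peaks at day {truth.probs[:, 0].argmax()}, "
          f"ends {truth.probs[0, 0] - truth.probs[-1, 0]:+.3f} below day 0")


if __name__ == "__main__":
    main()
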