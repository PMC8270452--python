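"""Synthetic opinion-stream generator.

Emulates the statistical structure of a year of vaccine-related posting:

* a baseline trinomial opinion split (favourable / contrary / undecided),
  by default (0.70, 0.164, 0.136);
* daily post volumes from a negative binomial background with explicit
  multiplicative spikes standing in for the few dominant news-driven peaks;
* short *events* that shift the favourable proportion additively for a few
  days (the contrary/undecided shares absorb the shift proportionally);
* a slow quadratic trend applied on the logit of the favourable proportion
  (so trajectories stay inside the simplex without clipping), with the
  contrary:undecided ratio held fixed;
* out-of-context chatter, duplicate posts and per-post engagement for
  exercising the ingestion stage, and noisy annotators for the agreement
  statistics.

Everything is driven by a single integer seed through spawned child
streams, so a scenario is reproducible end to end and the post-level and
day-level views of the same scenario share identical polarity counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .agreement import AnnotationMatrix
from .ingest import DailyPolaritySeries, PostRecord

logger = logging.getLogger(__name__)

BASELINE_PROBS = (0.70, 0.164, 0.136)


@dataclass(frozen=True)
class EventSpec:
    """A transient opinion shock: p_F += delta_f for duration days."""

    start_day: int
    duration_days: int
    delta_f: float


@dataclass(frozen=True)
class VolumeSpike:
    """A single day whose expected volume is multiplied."""

    day: int
    multiplier: float


@dataclass
class ScenarioConfig:
    """Full parametrization of a synthetic opinion stream."""

    n_days: int = 365
    start: date = date(2018, 1, 1)
    baseline_probs: tuple[float, float, float] = BASELINE_PROBS
    volume_mean: float = 200.0
    volume_dispersion: float = 10.0
    spikes: tuple[VolumeSpike, ...] = ()
    events: tuple[EventSpec, ...] = ()
    trend: tuple[float, float, float] = (0.0, 0.0, 0.0)  # logit-scale (a, b, c)
    engagement_mean: float = 2.0
    engagement_dispersion: float = 0.25
    ooc_fraction: float = 0.578
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be positive")
        p = np.asarray(self.baseline_probs, dtype=float)
        if (p <= 0).any() or abs(p.sum() - 1) > 1e-9:
            raise ValueError("baseline_probs must be interior to the simplex")
        if self.volume_mean <= 0:
            raise ValueError("volume mean must be positive")
        if not 0 <= self.ooc_fraction < 1:
            raise ValueError("ooc_fraction must be in [0, 1)")
        self.spikes = tuple(VolumeSpike(**s) if isinstance(s, dict) else s
                            for s in self.spikes)
        self.events = tuple(EventSpec(**e) if isinstance(e, dict) else e
                            for e in self.events)
        if isinstance(self.start, str):
            self.start = date.fromisoformat(self.start)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["start"] = self.start.isoformat()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("baseline_probs", "trend"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """The noiseless state behind a generated scenario."""

    probs: np.ndarray  # (n_days, 3) true daily probability vectors
    event_flags: np.ndarray  # bool, day under an active event
    trend_coefficients: tuple[float, float, float]
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "probs": self.probs.tolist(),
                "event_flags": self.event_flags.astype(bool).tolist(),
                "trend_coefficients": list(self.trend_coefficients),
                "seed": self.seed,
            }, fh)


def truth_probabilities(config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic daily probability vectors p(t) and event flags.

    The quadratic trend acts on logit(p_F) over the centered unit time
    u = 2t/(T-1) - 1; the contrary:undecided ratio is preserved when the
    favourable share moves.  Events then shift p_F additively.  A
    composition that leaves the open simplex raises with the offending days.
    """
    n = config.n_days
    base = np.asarray(config.baseline_probs, dtype=float)
    a, b, c = config.trend
    if n > 1:
        u = 2.0 * np.arange(n) / (n - 1) - 1.0
    else:
        u = np.zeros(1)
    p_f = expit(logit(base[0]) + a + b * u + c * u ** 2)
    flags = np.zeros(n, dtype=bool)
    for ev in config.events:
        sl = slice(max(0, ev.start_day), min(n, ev.start_day + ev.duration_days))
        p_f[sl] += ev.delta_f
        flags[sl] = True
    bad = np.flatnonzero((p_f <= 0) | (p_f >= 1))
    if bad.size:
        raise ValueError(
            f"degenerate probability vector on days {bad.tolist()[:10]}"
            f"{'...' if bad.size > 10 else ''}")
    ratio = base[1] / (base[1] + base[2])
    rest = 1.0 - p_f
    probs = np.column_stack([p_f, rest * ratio, rest * (1 - ratio)])
    return probs, flags


def _streams(seed: int, n: int = 4) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in children]


def generate_series(config: ScenarioConfig, seed: int | None = None
                    ) -> tuple[DailyPolaritySeries, SyntheticTruth]:
    """Draw a daily polarity series from a scenario.

    Volumes are negative binomial around the (possibly spiked) daily mean,
    counts are multinomial around the truth trajectory, and interactions
    add a heavy-tailed engagement total on top of the volume.
    """
    used_seed = config.seed if seed is None else seed
    probs, flags = truth_probabilities(config)
    vol_rng, count_rng, inter_rng, _ = _streams(used_seed)

    means = np.full(config.n_days, config.volume_mean)
    for sp in config.spikes:
        if 0 <= sp.day < config.n_days:
            means[sp.day] *= sp.multiplier
    k = config.volume_dispersion
    volumes = vol_rng.negative_binomial(k, k / (k + means))

    counts = np.zeros((config.n_days, 3), dtype=int)
    for t in range(config.n_days):
        if volumes[t] > 0:
            counts[t] = count_rng.multinomial(volumes[t], probs[t])

    # engagement: per-day total likes+retweets ~ NB with heavy tail
    ke = config.engagement_dispersion
    mean_extra = np.maximum(volumes * config.engagement_mean, 1e-9)
    extra = inter_rng.negative_binomial(ke, ke / (ke + mean_extra))
    interactions = volumes + extra

    series = DailyPolaritySeries.from_arrays(config.start, counts, interactions)
    truth = SyntheticTruth(probs=probs, event_flags=flags,
                           trend_coefficients=config.trend, seed=used_seed)
    return series, truth


def generate_posts(config: ScenarioConfig, seed: int | None = None
                   ) -> tuple[list[PostRecord], SyntheticTruth]:
    """Expand a scenario into individual post records.

    The polarity counts per day are identical to :func:`generate_series`
    under the same seed (the series is drawn first, then expanded), while
    timestamps, engagement, out-of-context posts and injected duplicates
    come from an independent child stream.
    """
    used_seed = config.seed if seed is None else seed
    series, truth = generate_series(config, seed=used_seed)
    post_rng = _streams(used_seed)[3]
    records: list[PostRecord] = []
    counts = series.counts
    f = config.ooc_fraction
    ke = config.engagement_dispersion
    uid = 0
    for t, ts in enumerate(series.dates):
        day_labels = (["F"] * int(counts[t, 0]) + ["C"] * int(counts[t, 1])
                      + ["U"] * int(counts[t, 2]))
        n_ret = len(day_labels)
        n_ooc = int(round(n_ret * f / (1 - f))) if f > 0 else 0
        day_labels += ["OOC"] * n_ooc
        secs = np.sort(post_rng.integers(0, 86400, size=len(day_labels)))
        mean_e = config.engagement_mean
        extras = post_rng.negative_binomial(ke, ke / (ke + mean_e),
                                            size=(len(day_labels), 2))
        for i, lab in enumerate(day_labels):
            rec = PostRecord(
                post_id=f"p{uid:08d}",
                timestamp=(ts + pd.Timedelta(seconds=int(secs[i]))).to_pydatetime(),
                label=lab,
                n_retweets=int(extras[i, 0]),
                n_likes=int(extras[i, 1]),
            )
            uid += 1
            records.append(rec)
            if config.duplicate_fraction > 0 and \
                    post_rng.random() < config.duplicate_fraction:
                records.append(rec)
    return records, truth


def generate_annotations(n_items: int, n_raters: int,
                         true_label_probs: Sequence[float],
                         confusion_matrices,
                         seed: int | None = None) -> AnnotationMatrix:
    """Simulate a multi-rater labelling campaign.

    Items get latent true labels from ``true_label_probs``; each rater's
    assigned label is drawn from their confusion-matrix row for that truth.
    ``confusion_matrices`` is one row-stochastic (K, K) matrix shared by all
    raters, or a sequence of one per rater.
    """
    p = np.asarray(true_label_probs, dtype=float)
    K = len(p)
    cms = np.asarray(confusion_matrices, dtype=float)
    if cms.ndim == 2:
        cms = np.repeat(cms[None], n_raters, axis=0)
    if cms.shape != (n_raters, K, K):
        raise ValueError("confusion matrices must be (n_raters, K, K) or (K, K)")
    if not np.allclose(cms.sum(axis=2), 1.0, atol=1e-9) or (cms < 0).any():
        raise ValueError("confusion matrices must be row-stochastic")
    rng = np.random.default_rng(seed)
    truths = rng.choice(K, size=n_items, p=p / p.sum())
    counts = np.zeros((n_items, K), dtype=int)
    for r in range(n_raters):
        # vectorised draw from each item's confusion row
        cum = np.cumsum(cms[r][truths], axis=1)
        draws = (rng.random(n_items)[:, None] < cum).argmax(axis=1)
        np.add.at(counts, (np.arange(n_items), draws), 1)
    from .agreement import CATEGORIES
    cats = CATEGORIES[:K] if K <= len(CATEGORIES) else tuple(str(i) for i in range(K))
    return AnnotationMatrix(counts, cats)


def calibration_experiment(config: ScenarioConfig, test: str = "basic",
                           n_replicates: int = 200,
                           alphas: Sequence[float] = (0.10, 0.05, 0.01),
                           seed: int = 0,
                           **test_kwargs) -> pd.DataFrame:
    """Monte Carlo calibration of a day-level test under a scenario.

    Runs ``n_replicates`` independent series and reports, per significance
    level: mean rejected days, the rejection fraction among tested days,
    and Monte Carlo standard errors (across replicates).  For a type-I
    error study the scenario should carry no events and no trend.
    """
    from . import daily_tests

    runners = {
        "basic": lambda s, rs: daily_tests.basic_daily_test(s, seed=rs, **test_kwargs),
        "running": lambda s, rs: daily_tests.running_daily_test(s, seed=rs,
                                                                **test_kwargs),
        "variance": lambda s, rs: daily_tests.running_variance_test(s, **test_kwargs),
    }
    if test not in runners:
        raise ValueError(f"unknown test {test!r}")
    rep_rej = np.zeros((n_replicates, len(alphas)))
    rep_frac = np.zeros((n_replicates, len(alphas)))
    tested = np.zeros(n_replicates)
    child = np.random.SeedSequence(seed).generate_state(2 * n_replicates) % (2 ** 31)
    for r in range(n_replicates):
        series, _ = generate_series(config, seed=int(child[2 * r]))
        res = runners[test](series, int(child[2 * r + 1]))
        summ = daily_tests.rejection_summary(res, alphas)
        rep_rej[r] = summ.rejected_days
        tested[r] = summ.tested_days
        rep_frac[r] = (np.asarray(summ.rejected_days) / summ.tested_days
                       if summ.tested_days else np.nan)
    rows = []
    for j, a in enumerate(alphas):
        rows.append({
            "alpha": a,
            "mean_rejected_days": float(rep_rej[:, j].mean()),
            "se_rejected_days": float(rep_rej[:, j].std(ddof=1)
                                      / np.sqrt(n_replicates)),
            "rejection_fraction": float(np.nanmean(rep_frac[:, j])),
            "se_rejection_fraction": float(np.nanstd(rep_frac[:, j], ddof=1)
                                           / np.sqrt(n_replicates)),
            "mean_tested_days": float(tested.mean()),
            "n_replicates": n_replicates,
        })
    return pd.DataFrame(rows)


def event_power_experiment(config: ScenarioConfig, window: int = 15,
                           alpha: float = 0.05, n_replicates: int = 20,
                           seed: int = 0, **test_kwargs) -> dict:
    """Power of the running multinomial test on event vs background days.

    Background days are those whose own day and whole preceding window are
    event-free, so the comparison is clean of null-contamination; days
    whose window overlaps an event but that are not themselves under one
    are reported separately as "contaminated".
    """
    from . import daily_tests

    if not config.events:
        raise ValueError("config has no events; nothing to measure power on")
    _, flags = truth_probabilities(config)
    n = config.n_days
    contaminated = np.zeros(n, dtype=bool)
    for t in range(n):
        lo = max(0, t - window)
        if flags[lo:t].any() and not flags[t]:
            contaminated[t] = True
    background = ~flags & ~contaminated

    hits = {"event": 0, "background": 0, "contaminated": 0}
    totals = {"event": 0, "background": 0, "contaminated": 0}
    child = np.random.SeedSequence(seed).generate_state(2 * n_replicates) % (2 ** 31)
    for r in range(n_replicates):
        series, _ = generate_series(config, seed=int(child[2 * r]))
        res = daily_tests.running_daily_test(series, window=window,
                                             seed=int(child[2 * r + 1]),
                                             **test_kwargs)
        ok = ~res["skipped"].to_numpy(dtype=bool)
        rej = ok & (res["p_value"].to_numpy() <= alpha)
        for name, mask in (("event", flags), ("background", background),
                           ("contaminated", contaminated)):
            totals[name] += int((ok & mask).sum())
            hits[name] += int((rej & mask).sum())
    return {
        "alpha": alpha,
        "window": window,
        "n_replicates": n_replicates,
        "event_rejection_fraction": hits["event"] / max(totals["event"], 1),
        "background_rejection_fraction":
            hits["background"] / max(totals["background"], 1),
        "contaminated_rejection_fraction":
            hits["contaminated"] / max(totals["contaminated"], 1),
        "tested_days": totals,
    }


def demo_scenario(seed: int = 0) -> ScenarioConfig:
    """A year-long scenario with the qualitative features of the observed
    corpus: baseline (0.70, 0.164, 0.136), three dominant volume peaks,
    short opinion shocks around them, and a slow rise-then-fall trend in
    the favourable share (peaking in late spring, down >7 points by
    December)."""
    return ScenarioConfig(
        n_days=365,
        baseline_probs=BASELINE_PROBS,
        volume_mean=200.0,
        volume_dispersion=10.0,
        spikes=(VolumeSpike(58, 12.0), VolumeSpike(151, 20.0),
                VolumeSpike(245, 8.0)),
        events=(EventSpec(55, 8, -0.10), EventSpec(148, 10, 0.08),
                EventSpec(242, 7, -0.07)),
        trend=(0.08, -0.16, -0.22),
        seed=seed,
    )
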