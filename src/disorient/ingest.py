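"""Ingestion of labelled post streams into daily polarity series.

A *post record* is one social-media post carrying a polarity label:
favourable (``F``), contrary (``C``), undecided (``U``) or out-of-context
(``OOC``).  OOC posts express no position on immunization and are dropped
before any polarity analysis.  The daily series carries, per calendar day,
the label counts (n_F, n_C, n_U), the retained post volume and the total
interaction count (posts + likes + retweets attributed to the posting day).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POLARITY_LABELS = ("F", "C", "U")
ALL_LABELS = POLARITY_LABELS + ("OOC",)


@dataclass(frozen=True)
class PostRecord:
    """One labelled post: id, UTC timestamp, polarity label, engagement."""

    post_id: str
    timestamp: datetime
    label: str
    n_retweets: int = 0
    n_likes: int = 0

    def __post_init__(self) -> None:
        if not self.post_id:
            raise ValueError("post_id must be non-empty")
        if self.label not in ALL_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.n_retweets < 0 or self.n_likes < 0:
            raise ValueError("interaction counts must be non-negative")


@dataclass
class DailyPolaritySeries:
    """Date-indexed daily polarity counts.

    ``data`` has one row per consecutive calendar day with columns
    ``n_F, n_C, n_U, volume, interactions``; days with no retained post are
    carried as explicit zero rows so that every window computation sees a
    gap-free axis.
    """

    data: pd.DataFrame

    COLUMNS = ("n_F", "n_C", "n_U", "volume", "interactions")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if not df.index.is_monotonic_increasing:
            raise ValueError("dates must be increasing")
        if len(df) > 1:
            deltas = np.diff(df.index.values).astype("timedelta64[D]")
            if not (deltas == np.timedelta64(1, "D")).all():
                raise ValueError("dates must be consecutive calendar days")
        if not (df["n_F"] + df["n_C"] + df["n_U"] == df["volume"]).all():
            raise ValueError("label counts must sum to volume on every day")
        if (df["interactions"] < df["volume"]).any():
            raise ValueError("interactions must be >= volume")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def counts(self) -> np.ndarray:
        """(n_days, 3) array of (n_F, n_C, n_U)."""
        return self.data[["n_F", "n_C", "n_U"]].to_numpy()

    @property
    def volume(self) -> np.ndarray:
        return self.data["volume"].to_numpy()

    def proportions(self) -> pd.DataFrame:
        """Daily proportion vectors; NaN on zero-volume days."""
        vol = self.data["volume"].to_numpy().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = self.counts / vol[:, None]
        props[vol == 0] = np.nan
        return pd.DataFrame(props, index=self.data.index, columns=["p_F", "p_C", "p_U"])

    def pooled_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DailyPolaritySeries":
        df = pd.read_csv(path, parse_dates=["date"])
        df = df.set_index("date")
        return cls(df[list(cls.COLUMNS)].astype(int))

    @classmethod
    def from_arrays(cls, start: date, counts: np.ndarray,
                    interactions: np.ndarray | None = None) -> "DailyPolaritySeries":
        counts = np.asarray(counts, dtype=int)
        volume = counts.sum(axis=1)
        if interactions is None:
            interactions = volume
        idx = pd.date_range(start=pd.Timestamp(start), periods=len(counts), freq="D")
        df = pd.DataFrame(
            {"n_F": counts[:, 0], "n_C": counts[:, 1], "n_U": counts[:, 2],
             "volume": volume, "interactions": np.asarray(interactions, dtype=int)},
            index=idx,
        )
        return cls(df)


@dataclass(frozen=True)
class PolaritySummary:
    """Pooled polarity proportions with bootstrap confidence intervals."""

    p_F: float
    p_C: float
    p_U: float
    ci_F: tuple[float, float]
    ci_C: tuple[float, float]
    ci_U: tuple[float, float]
    p_hesitant: float
    ci_hesitant: tuple[float, float]
    ci_level: float
    ci_method: str

    def to_dict(self) -> dict:
        return {
            "p_F": self.p_F, "p_C": self.p_C, "p_U": self.p_U,
            "ci_F": list(self.ci_F), "ci_C": list(self.ci_C), "ci_U": list(self.ci_U),
            "p_hesitant": self.p_hesitant, "ci_hesitant": list(self.ci_hesitant),
            "ci_level": self.ci_level, "ci_method": self.ci_method,
        }


def read_posts_csv(path) -> list[PostRecord]:
    """Read post records from CSV, rejecting malformed rows with a logged count.

    Expected header: ``post_id,timestamp,label,n_retweets,n_likes`` with
    ISO-8601 timestamps.
    """
    df = pd.read_csv(path, dtype={"post_id": str})
    records: list[PostRecord] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            ts = pd.Timestamp(row.timestamp)
            if ts.tzinfo is None:
                ts = ts.tz_localize("UTC")
            rec = PostRecord(
                post_id=str(row.post_id),
                timestamp=ts.to_pydatetime(),
                label=str(row.label),
                n_retweets=int(row.n_retweets),
                n_likes=int(row.n_likes),
            )
        except (ValueError, TypeError):
            n_rejected += 1
            continue
        records.append(rec)
    if n_rejected:
        logger.info("rejected %d malformed post rows", n_rejected)
    return records


def write_posts_csv(records: Sequence[PostRecord], path) -> None:
    df = pd.DataFrame(
        {
            "post_id": [r.post_id for r in records],
            "timestamp": [r.timestamp.isoformat() for r in records],
            "label": [r.label for r in records],
            "n_retweets": [r.n_retweets for r in records],
            "n_likes": [r.n_likes for r in records],
        }
    )
    df.to_csv(path, index=False)


def deduplicate(records: Iterable[PostRecord], drop_ooc: bool = True) -> list[PostRecord]:
    """Remove duplicate post ids (first occurrence wins); drop OOC posts.

    Mirrors the cleaning stage of a labelled-tweet corpus: the post id is
    the deduplication key, and out-of-context posts leave the polarity
    stream entirely (set ``drop_ooc=False`` to keep them for interaction
    accounting).
    """
    seen: set[str] = set()
    out: list[PostRecord] = []
    n_dup = 0
    n_ooc = 0
    for rec in records:
        if rec.post_id in seen:
            n_dup += 1
            continue
        seen.add(rec.post_id)
        if drop_ooc and rec.label == "OOC":
            n_ooc += 1
            continue
        out.append(rec)
    if n_dup or n_ooc:
        logger.info("deduplicate: removed %d duplicates, %d OOC posts", n_dup, n_ooc)
    return out


def aggregate_daily(records: Sequence[PostRecord], start: date, end: date,
                    tz_offset_hours: float = 0.0) -> DailyPolaritySeries:
    """Bin deduplicated records into a gap-free daily polarity series.

    Each post lands on exactly one calendar day (UTC midnight boundary,
    shiftable by ``tz_offset_hours``).  Likes and retweets are attributed
    to the posting day.  Posts outside [start, end] are excluded and their
    count logged.
    """
    if end < start:
        raise ValueError("empty date range: end precedes start")
    offset = timedelta(hours=tz_offset_hours)
    idx = pd.date_range(pd.Timestamp(start), pd.Timestamp(end), freq="D")
    day_pos = {d.date(): i for i, d in enumerate(idx)}
    counts = np.zeros((len(idx), 3), dtype=int)
    volume = np.zeros(len(idx), dtype=int)
    inter = np.zeros(len(idx), dtype=int)
    n_outside = 0
    lab_pos = {lab: j for j, lab in enumerate(POLARITY_LABELS)}
    for rec in records:
        ts = rec.timestamp
        if ts.tzinfo is not None:
            ts = ts.astimezone(timezone.utc).replace(tzinfo=None)
        d = (ts + offset).date()
        i = day_pos.get(d)
        if i is None:
            n_outside += 1
            continue
        volume[i] += 1
        inter[i] += 1 + rec.n_likes + rec.n_retweets
        j = lab_pos.get(rec.label)
        if j is not None:
            counts[i, j] += 1
    if n_outside:
        logger.info("aggregate_daily: excluded %d posts outside range", n_outside)
    # OOC records (if retained upstream) contribute to interactions only;
    # keep the count identity by restricting volume to polarity labels.
    volume = counts.sum(axis=1) + 0
    df = pd.DataFrame(
        {"n_F": counts[:, 0], "n_C": counts[:, 1], "n_U": counts[:, 2],
         "volume": volume, "interactions": np.maximum(inter, volume)},
        index=idx,
    )
    return DailyPolaritySeries(df)


def polarity_summary(series: DailyPolaritySeries, ci_method: str = "bootstrap",
                     ci_level: float = 0.95, n_boot: int = 2000,
                     seed: int | None = None,
                     day_blocked: bool = False) -> PolaritySummary:
    """Pooled polarity proportions over the whole period with bootstrap CIs.

    The default resamples posts (equivalently, multinomial resampling of the
    pooled label counts); ``day_blocked=True`` resamples whole days with
    replacement instead, which respects day-level clustering.
    """
    pooled = series.pooled_counts()
    total = int(pooled.sum())
    if total == 0:
        raise ValueError("zero total volume: no retained posts")
    p = pooled / total
    rng = np.random.default_rng(seed)
    alpha = 1.0 - ci_level
    if day_blocked:
        daily = series.counts
        n_days = len(daily)
        picks = rng.integers(0, n_days, size=(n_boot, n_days))
        boot_counts = daily[picks].sum(axis=1)  # (n_boot, 3)
    else:
        boot_counts = rng.multinomial(total, p, size=n_boot)
    tot = boot_counts.sum(axis=1, keepdims=True).astype(float)
    tot[tot == 0] = np.nan
    boot_p = boot_counts / tot
    qs = np.nanpercentile(boot_p, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    boot_hes = boot_p[:, 1] + boot_p[:, 2]
    hq = np.nanpercentile(boot_hes, [100 * alpha / 2, 100 * (1 - alpha / 2)])

    def _ci(j: int) -> tuple[float, float]:
        lo, hi = float(qs[0, j]), float(qs[1, j])
        # percentile interval; widen to the point estimate if bootstrap is degenerate
        return (min(lo, p[j]), max(hi, p[j]))

    hes = float(p[1] + p[2])
    return PolaritySummary(
        p_F=float(p[0]), p_C=float(p[1]), p_U=float(p[2]),
        ci_F=_ci(0), ci_C=_ci(1), ci_U=_ci(2),
        p_hesitant=hes,
        ci_hesitant=(min(float(hq[0]), hes), max(float(hq[1]), hes)),
        ci_level=ci_level,
        ci_method="day_blocked_bootstrap" if day_blocked else "post_bootstrap",
    )
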