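"""Day-level tests for short-term collective disorientation.

Each day's polarity count vector (n_F, n_C, n_U) is treated as a draw from
a trinomial population, and three tests probe whether the day is compatible
with an appropriate notion of "average opinion":

* the **basic test** takes the pooled yearly proportions as the null;
* the **running test** rebuilds the null for every day from the average
  daily proportions of the preceding ``window`` days, so it reacts to fast
  opinion shifts rather than slow drift;
* the **running-variance test** compares the trailing-window variance of
  the favourable proportion against the whole-period variance with a
  chi-square statistic, flagging both unusually turbulent and unusually
  frozen stretches.

The multinomial p-value is the exact conditional one — the total probability
of all outcome vectors no more probable than the observed one — computed by
full enumeration of the three-part compositions of n, with a seeded Monte
Carlo fallback above a configurable enumeration cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

DEFAULT_MAX_EXACT_N = 2000
DEFAULT_N_SIM = 10_000
#: relative log-probability slack treating numerically tied outcomes as ties
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class MultinomialNull:
    """A trinomial null hypothesis (pi_F, pi_C, pi_U) and its provenance."""

    probs: tuple[float, float, float]
    source: str = "yearly"

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if (p < -1e-12).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"null probabilities must lie on the simplex: {self.probs}")


@lru_cache(maxsize=64)
def _compositions(n: int) -> np.ndarray:
    """All (x1, x2, x3) with x1+x2+x3 = n, as an (m, 3) int array."""
    x1 = np.repeat(np.arange(n + 1), np.arange(n + 1, 0, -1))
    x2 = np.concatenate([np.arange(n - k + 1) for k in range(n + 1)])
    out = np.column_stack([x1, x2, n - x1 - x2])
    out.setflags(write=False)
    return out


@lru_cache(maxsize=64)
def _log_fact_sum(n: int) -> np.ndarray:
    """sum_i log(x_i!) per composition of n (null-independent, cached)."""
    out = gammaln(_compositions(n) + 1).sum(axis=1)
    out.setflags(write=False)
    return out


def _log_pmf(x: np.ndarray, n: int, probs: np.ndarray) -> np.ndarray:
    """Multinomial log pmf, vectorised over rows of x; -inf where impossible."""
    x = np.atleast_2d(x)
    logp = np.full(3, -np.inf)
    pos = probs > 0
    logp[pos] = np.log(probs[pos])
    with np.errstate(invalid="ignore"):
        terms = np.where(x == 0, 0.0, x * logp)  # 0 * log 0 := 0
    return gammaln(n + 1) - gammaln(x + 1).sum(axis=1) + terms.sum(axis=1)


def _log_pmf_all_compositions(n: int, probs: np.ndarray) -> np.ndarray:
    """Log pmf over every composition of n, reusing the cached factorial term."""
    comps = _compositions(n)
    if (probs > 0).all():
        terms = comps @ np.log(probs)
    else:
        logp = np.full(3, -np.inf)
        pos = probs > 0
        logp[pos] = np.log(probs[pos])
        with np.errstate(invalid="ignore"):
            terms = np.where(comps == 0, 0.0, comps * logp).sum(axis=1)
    return gammaln(n + 1) - _log_fact_sum(n) + terms


def exact_multinomial_pvalue(counts: Sequence[int], null: MultinomialNull,
                             max_n: int = DEFAULT_MAX_EXACT_N) -> float:
    """Exact multinomial goodness-of-fit p-value by full enumeration.

    p = sum of P(x) over all three-part compositions x of n with
    P(x) <= P(observed), ties included.  Outcomes that are impossible under
    the null contribute zero mass, so an observed count in a zero-probability
    category yields p = 0.
    """
    x = np.asarray(counts, dtype=int)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    n = int(x.sum())
    if n < 1:
        raise ValueError("need at least one observation")
    if n > max_n:
        raise ValueError(
            f"n={n} exceeds enumeration cap {max_n}; use mc_multinomial_pvalue")
    probs = np.asarray(null.probs, dtype=float)
    lp = _log_pmf_all_compositions(n, probs)
    lp_obs = _log_pmf(x, n, probs)[0]
    if np.isneginf(lp_obs):
        return 0.0
    mask = lp <= lp_obs + _TIE_TOL
    return float(min(1.0, np.exp(lp[mask]).sum()))


def mc_multinomial_pvalue(counts: Sequence[int], null: MultinomialNull,
                          n_sim: int = DEFAULT_N_SIM,
                          seed: int | np.random.Generator | None = None) -> float:
    """Monte Carlo multinomial p-value with the add-one correction.

    p = (1 + #{simulated outcomes with P <= P(observed)}) / (1 + n_sim);
    reproducible for a fixed seed, never exactly zero.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")
    x = np.asarray(counts, dtype=int)
    n = int(x.sum())
    if n < 1:
        raise ValueError("need at least one observation")
    probs = np.asarray(null.probs, dtype=float)
    lp_obs = _log_pmf(x, n, probs)[0]
    if np.isneginf(lp_obs):
        return 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sims = rng.multinomial(n, probs, size=n_sim)
    lp_sim = _log_pmf(sims, n, probs)
    hits = int((lp_sim <= lp_obs + _TIE_TOL).sum())
    return (1 + hits) / (1 + n_sim)


def multinomial_pvalue(counts: Sequence[int], null: MultinomialNull,
                       max_exact_n: int = DEFAULT_MAX_EXACT_N,
                       n_sim: int = DEFAULT_N_SIM,
                       seed: int | np.random.Generator | None = None
                       ) -> tuple[float, str]:
    """Dispatch to the exact test when enumeration is feasible, else Monte Carlo."""
    n = int(np.asarray(counts).sum())
    if n <= max_exact_n:
        return exact_multinomial_pvalue(counts, null, max_n=max_exact_n), "exact"
    return mc_multinomial_pvalue(counts, null, n_sim=n_sim, seed=seed), "monte_carlo"


_RESULT_COLUMNS = ["date", "method", "p_value", "statistic", "direction",
                   "null_F", "null_C", "null_U", "skipped", "skip_reason"]


def _empty_results() -> pd.DataFrame:
    return pd.DataFrame(columns=_RESULT_COLUMNS)


def basic_daily_test(series, min_volume: int = 1,
                     max_exact_n: int = DEFAULT_MAX_EXACT_N,
                     n_sim: int = DEFAULT_N_SIM,
                     seed: int | None = None) -> pd.DataFrame:
    """Test every day against the pooled whole-period polarity proportions.

    Returns one row per day with the p-value (statistic = probability of the
    observed vector under the null); days with volume below ``min_volume``
    are marked skipped.
    """
    pooled = series.pooled_counts()
    total = pooled.sum()
    if total == 0:
        raise ValueError("series has zero total volume")
    null = MultinomialNull(tuple(pooled / total), source="yearly")
    rng = np.random.default_rng(seed)
    return _run_fixed_null_tests(series, lambda i: null, min_volume,
                                 max_exact_n, n_sim, rng)


def running_daily_test(series, window: int = 15, min_history: int = 5,
                       pooled_null: bool = False,
                       min_volume: int = 1,
                       max_exact_n: int = DEFAULT_MAX_EXACT_N,
                       n_sim: int = DEFAULT_N_SIM,
                       seed: int | None = None) -> pd.DataFrame:
    """Test every day against the average proportions of the preceding window.

    The null for day t is built from days (t-window, t): by default the
    unweighted mean of the non-empty daily proportion vectors ("average
    preferences persistence"); with ``pooled_null=True`` the window's counts
    are pooled instead, weighting days by volume.  Days with fewer than
    ``min_history`` non-empty days in their window are skipped.
    """
    if window < 2:
        raise ValueError("window must be at least 2")
    counts = series.counts
    vol = series.volume
    with np.errstate(invalid="ignore", divide="ignore"):
        props = counts / vol[:, None].astype(float)

    def null_for(i: int) -> MultinomialNull | str:
        lo = max(0, i - window)
        if i < window:
            return "insufficient history"
        idx = [j for j in range(lo, i) if vol[j] > 0]
        if len(idx) < min_history:
            return "insufficient history"
        if pooled_null:
            pooled = counts[idx].sum(axis=0)
            p = pooled / pooled.sum()
        else:
            p = props[idx].mean(axis=0)
        return MultinomialNull(tuple(p), source=f"running({window})")

    rng = np.random.default_rng(seed)
    return _run_fixed_null_tests(series, null_for, min_volume,
                                 max_exact_n, n_sim, rng)


def _run_fixed_null_tests(series, null_for, min_volume: int,
                          max_exact_n: int, n_sim: int,
                          rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    counts = series.counts
    vol = series.volume
    for i, ts in enumerate(series.dates):
        base = {"date": ts, "method": None, "p_value": np.nan,
                "statistic": np.nan, "direction": "",
                "null_F": np.nan, "null_C": np.nan, "null_U": np.nan,
                "skipped": True, "skip_reason": ""}
        if vol[i] < max(min_volume, 1):
            base["skip_reason"] = "volume below threshold"
            rows.append(base)
            continue
        null = null_for(i)
        if isinstance(null, str):
            base["skip_reason"] = null
            rows.append(base)
            continue
        p, method = multinomial_pvalue(counts[i], null, max_exact_n=max_exact_n,
                                       n_sim=n_sim, seed=rng)
        probs = np.asarray(null.probs)
        base.update({
            "method": method, "p_value": p,
            "statistic": float(np.exp(_log_pmf(counts[i], int(vol[i]), probs)[0])),
            "null_F": null.probs[0], "null_C": null.probs[1], "null_U": null.probs[2],
            "skipped": False,
        })
        rows.append(base)
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def variance_test_from_proportions(p_f: np.ndarray, window: int = 15,
                                   dates=None) -> pd.DataFrame:
    """Chi-square running-variance test on a favourable-proportion sequence.

    For each position t, the sample variance of the last ``window``
    non-missing values (ending at t) is compared to the whole-sequence
    variance sigma0^2 via T = (w-1) s_w^2 / sigma0^2 ~ chi-square(w-1);
    the p-value is two-sided (both turbulent and frozen windows reject) and
    the direction column records which tail the window sits in.
    """
    if window < 3:
        raise ValueError("window must be at least 3")
    p_f = np.asarray(p_f, dtype=float)
    obs_idx = np.flatnonzero(~np.isnan(p_f))
    if len(obs_idx) < 2:
        raise ValueError("need at least two observed days")
    sigma0_sq = float(np.var(p_f[obs_idx], ddof=1))
    if sigma0_sq == 0:
        raise ValueError("whole-period variance is zero")
    if dates is None:
        dates = np.arange(len(p_f))
    pos_in_obs = {int(j): k for k, j in enumerate(obs_idx)}
    rows = []
    for t in range(len(p_f)):
        base = {"date": dates[t], "method": "chi2_variance", "p_value": np.nan,
                "statistic": np.nan, "direction": "",
                "null_F": np.nan, "null_C": np.nan, "null_U": np.nan,
                "skipped": True, "skip_reason": ""}
        k = pos_in_obs.get(t)
        if k is None:
            base["skip_reason"] = "no observation"
            rows.append(base)
            continue
        if k + 1 < window:
            base["skip_reason"] = "insufficient history"
            rows.append(base)
            continue
        win = p_f[obs_idx[k + 1 - window: k + 1]]
        s_sq = float(np.var(win, ddof=1))
        t_stat = (window - 1) * s_sq / sigma0_sq
        cdf = stats.chi2.cdf(t_stat, df=window - 1)
        p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
        base.update({"p_value": p, "statistic": t_stat,
                     "direction": "high" if cdf > 0.5 else "low",
                     "skipped": False, "skip_reason": ""})
        rows.append(base)
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def running_variance_test(series, window: int = 15) -> pd.DataFrame:
    """Running-variance test of the daily favourable proportion (see
    :func:`variance_test_from_proportions`); zero-volume days are skipped."""
    props = series.proportions()
    return variance_test_from_proportions(
        props["p_F"].to_numpy(), window=window, dates=list(series.dates))


@dataclass(frozen=True)
class TestSummary:
    """Rejection-day counts per significance level vs the chance expectation."""

    alphas: tuple[float, ...]
    rejected_days: tuple[int, ...]
    expected_days: tuple[float, ...]
    tested_days: int
    skipped_days: int

    def to_dict(self) -> dict:
        return {
            "alphas": list(self.alphas),
            "rejected_days": list(self.rejected_days),
            "expected_days": list(self.expected_days),
            "tested_days": self.tested_days,
            "skipped_days": self.skipped_days,
        }

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "alpha": self.alphas,
            "rejected_days": self.rejected_days,
            "expected_days": self.expected_days,
            "tested_days": self.tested_days,
        })


DEFAULT_ALPHAS = (0.10, 0.05, 0.01)


def rejection_summary(results: pd.DataFrame,
                      alphas: Iterable[float] = DEFAULT_ALPHAS) -> TestSummary:
    """Count rejection days per alpha and the count expected by chance alone.

    The pipeline deliberately reports raw per-day rejections against
    alpha * tested_days rather than multiplicity-adjusted ones: the evidence
    of disorientation is the excess of rejection days over that expectation.
    """
    alphas = tuple(alphas)
    if len(results) == 0:
        return TestSummary(alphas, tuple(0 for _ in alphas),
                           tuple(0.0 for _ in alphas), 0, 0)
    tested = results[~results["skipped"].astype(bool)]
    n_tested = len(tested)
    rejected = tuple(int((tested["p_value"] <= a).sum()) for a in alphas)
    expected = tuple(float(a * n_tested) for a in alphas)
    return TestSummary(alphas, rejected, expected, n_tested,
                       int(len(results) - n_tested))


def window_sensitivity(series, windows: Sequence[int],
                       alphas: Iterable[float] = DEFAULT_ALPHAS,
                       min_history: int = 5,
                       seed: int | None = None) -> pd.DataFrame:
    """Re-run the running multinomial and running-variance tests per window.

    Returns a long table (window, test, alpha, rejected_days, expected_days,
    tested_days) for judging how sensitive the rejection counts are to the
    somewhat arbitrary choice of window length.
    """
    rows = []
    for w in windows:
        for name, res in (
            ("running_multinomial",
             running_daily_test(series, window=w, min_history=min(min_history, w),
                                seed=seed)),
            ("running_variance",
             running_variance_test(series, window=max(w, 3))),
        ):
            summ = rejection_summary(res, alphas)
            for a, r, e in zip(summ.alphas, summ.rejected_days, summ.expected_days):
                rows.append({"window": w, "test": name, "alpha": a,
                             "rejected_days": r, "expected_days": e,
                             "tested_days": summ.tested_days})
    return pd.DataFrame(rows, columns=["window", "test", "alpha", "rejected_days",
                                       "expected_days", "tested_days"])
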