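"""Inter-annotator agreement statistics for the labelled training set.

Manual polarity labels are only trustworthy up to annotator noise, so the
pipeline qualifies them with two statistics: the raw pairwise labelling
accuracy (share of doubly-annotated items on which two raters agree, with
an exact Clopper-Pearson binomial interval) and Fleiss' kappa, the
chance-corrected agreement for many raters over categorical labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats import inter_rater
from statsmodels.stats.proportion import proportion_confint

CATEGORIES = ("F", "C", "U", "OOC")


@dataclass
class AnnotationMatrix:
    """Items x categories table of rater counts.

    Entry (i, j) is the number of raters who assigned category j to item i;
    every row sums to the same number of raters per item.
    """

    counts: np.ndarray
    categories: tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D items x categories table")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        row_sums = self.counts.sum(axis=1)
        if len(row_sums) == 0:
            raise ValueError("need at least one item")
        if not (row_sums == row_sums[0]).all():
            raise ValueError("every item must have the same number of raters")
        if row_sums[0] < 2:
            raise ValueError("need at least two raters per item")

    @property
    def n_raters_per_item(self) -> int:
        return int(self.counts.sum(axis=1)[0])

    @classmethod
    def from_long(cls, df: pd.DataFrame,
                  categories: Sequence[str] = CATEGORIES) -> "AnnotationMatrix":
        """Build from a long table with columns item_id, rater_id, label."""
        pivot = (
            df.groupby(["item_id", "label"]).size().unstack(fill_value=0)
            .reindex(columns=list(categories), fill_value=0)
        )
        return cls(pivot.to_numpy(), tuple(categories))


@dataclass(frozen=True)
class AgreementResult:
    accuracy: float
    accuracy_ci: tuple[float, float]
    kappa: float

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy,
                "accuracy_ci": list(self.accuracy_ci),
                "kappa": self.kappa}


def fleiss_kappa(matrix: AnnotationMatrix) -> float:
    """Fleiss' kappa: (P-bar - Pe-bar) / (1 - Pe-bar).

    Per-item agreement is the share of concordant rater pairs and chance
    agreement is the sum of squared marginal category shares.  When all
    rating mass sits in a single category, chance agreement is 1 and the
    ratio is indeterminate; unanimity is then perfect agreement (kappa 1),
    anything else is an error.
    """
    counts = matrix.counts
    n = matrix.n_raters_per_item
    marg = counts.sum(axis=0) / counts.sum()
    p_e = float((marg ** 2).sum())
    if p_e >= 1.0 - 1e-15:
        p_bar = float((((counts ** 2).sum(axis=1) - n) / (n * (n - 1))).mean())
        if p_bar >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("degenerate table: single category with imperfect agreement")
    return float(inter_rater.fleiss_kappa(counts, method="fleiss"))


def pairwise_accuracy(pairs: Sequence[tuple[str, str]],
                      ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Fraction of label pairs that agree, with a Clopper-Pearson interval."""
    if len(pairs) == 0:
        raise ValueError("need at least one pair")
    n = len(pairs)
    k = sum(1 for a, b in pairs if a == b)
    lo, hi = proportion_confint(k, n, alpha=1 - ci_level, method="beta")
    return k / n, (float(lo), float(hi))


def within_item_pairs(df: pd.DataFrame) -> list[tuple[str, str]]:
    """All unordered rater-label pairs within each multiply-annotated item."""
    pairs: list[tuple[str, str]] = []
    for _, grp in df.groupby("item_id"):
        labels = list(grp["label"])
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                pairs.append((labels[i], labels[j]))
    return pairs


def agreement_report(df: pd.DataFrame, ci_level: float = 0.95) -> AgreementResult:
    """Accuracy + kappa from a long annotation table (item_id, rater_id, label)."""
    matrix = AnnotationMatrix.from_long(df)
    acc, ci = pairwise_accuracy(within_item_pairs(df), ci_level=ci_level)
    return AgreementResult(accuracy=acc, accuracy_ci=ci, kappa=fleiss_kappa(matrix))
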