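"""Agreement statistics for in-vivo vs ground-truth / ex-vivo comparisons.

Pearson correlation (two-sided p-value from the t transform), Bland-Altman
mean difference +/- sample SD with 1.96-SD limits of agreement, and
per-quadrant mean +/- SD cohort summaries. The Bland-Altman sign convention
is predicted minus reference, so a positive mean difference reads as an
overestimation by the automatic method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .elasticity import QUADRANT_ORDER

__all__ = ["AgreementStats", "QuadrantSummary", "pearson", "bland_altman", "quadrant_summary"]


@dataclass
class AgreementStats:
    """Correlation and/or difference statistics for one paired comparison."""

    n: int
    r: float | None = None
    p_value: float | None = None
    mean_diff: float | None = None
    sd_diff: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None

    def to_json_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    return x, y


def pearson(x, y, method: str = "pearson") -> AgreementStats:
    """Sample correlation with two-sided p-value (``method='spearman'`` optional)."""
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a correlation p-value")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AgreementStats(n=int(x.size), r=float(res.statistic), p_value=float(res.pvalue))


def bland_altman(x, y) -> AgreementStats:
    """Mean and sample SD of the paired differences x - y, with 1.96-SD limits.

    Call as ``bland_altman(predicted, reference)`` so positive mean differences
    mean the method overestimates.
    """
    x, y = _paired(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementStats(
        n=int(x.size),
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
    )


def bland_altman_plot_data(x, y) -> pd.DataFrame:
    """Pairwise means vs differences, ready for a Bland-Altman scatter."""
    x, y = _paired(x, y)
    return pd.DataFrame({"mean": (x + y) / 2.0, "diff": x - y})


@dataclass
class QuadrantSummary:
    """Cohort mean +/- SD per quadrant for one or more metrics.

    ``table`` is indexed by quadrant in canonical order (medial, anterior,
    lateral, posterior) with a (metric, mean|std) column MultiIndex.
    """

    table: pd.DataFrame

    def to_json_dict(self) -> dict:
        out: dict = {}
        for metric in self.table.columns.levels[0]:
            out[metric] = {
                q: {
                    "mean": float(self.table.loc[q, (metric, "mean")]),
                    "std": float(self.table.loc[q, (metric, "std")]),
                }
                for q in self.table.index
            }
        return out


def quadrant_summary(per_subject: pd.DataFrame | dict) -> QuadrantSummary:
    """Summarise per-subject per-quadrant values as mean +/- sample SD.

    ``per_subject`` maps metric name -> DataFrame (rows subjects, columns the
    four quadrants), or is a single such DataFrame (metric named "value").
    Every subject must have all four quadrants; SD uses the n-1 denominator.
    """
    if isinstance(per_subject, pd.DataFrame):
        per_subject = {"value": per_subject}
    blocks = {}
    for metric, df in per_subject.items():
        missing = set(QUADRANT_ORDER) - set(df.columns)
        if missing:
            raise ValueError(f"metric {metric!r} missing quadrants: {sorted(missing)}")
        df = df[list(QUADRANT_ORDER)]
        if df.isna().any().any():
            bad = df.index[df.isna().any(axis=1)].tolist()
            raise ValueError(f"metric {metric!r}: subjects with missing quadrants: {bad}")
        blocks[metric] = pd.DataFrame(
            {"mean": df.mean(axis=0), "std": df.std(axis=0, ddof=1)}
        )
    table = pd.concat(blocks, axis=1)
    table.index.name = "quadrant"
    return QuadrantSummary(table=table.loc[list(QUADRANT_ORDER)])
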