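"""Mendelian segregation goodness-of-fit.

Selfing a heterozygous T-DNA insertion line is expected to yield genotypes
in a 1:2:1 WT : heterozygous : homozygous ratio; departure is tested with
the Pearson chi-square statistic sum (O - E)^2 / E against expected counts
E_i = n * w_i / sum(w), df = k - 1, with NO continuity correction.  For the
canonical worked example — observed (8, 2, 0) against 1:2:1 — this gives
12.1 + 1.8 + 2.5 = 16.4 on 2 df (p < 0.05); a Yates-corrected statistic
would give 12.85 instead, so the uncorrected form is the one implemented.

Expected counts below 5 are common at these sample sizes (n = 8–10 plants);
they trigger a warning about chi-square approximation quality, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SegregationTable", "ChiSquareResult", "chisq_segregation",
           "chisq_from_csv"]

DEFAULT_RATIO = (1.0, 2.0, 1.0)


@dataclass(frozen=True)
class SegregationTable:
    """Ordered genotype counts (WT, heterozygous, homozygous) for one line."""

    counts: tuple[int, ...]
    expected_ratio: tuple[float, ...] = DEFAULT_RATIO
    line_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        w = np.asarray(self.expected_ratio)
        if len(c) != len(w):
            raise ValueError("counts and expected_ratio must have equal length")
        if (c < 0).any() or c.sum() < 1:
            raise ValueError("counts must be non-negative with total >= 1")
        if (w <= 0).any():
            raise ValueError("expected_ratio weights must be positive")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chisq_segregation(table: SegregationTable) -> ChiSquareResult:
    """Pearson chi-square of observed counts against the expected ratio."""
    obs = np.asarray(table.counts, dtype=float)
    w = np.asarray(table.expected_ratio, dtype=float)
    expected = obs.sum() * w / w.sum()
    if (expected < 5).any():
        warnings.warn(
            f"expected count below 5 (min {expected.min():.2f}); the "
            "chi-square approximation may be poor at this sample size",
            UserWarning, stacklevel=2)
    stat, p = stats.chisquare(obs, f_exp=expected)
    return ChiSquareResult(float(stat), len(obs) - 1, float(p))


def chisq_from_csv(path: str | Path,
                   ratio: Sequence[float] = DEFAULT_RATIO) -> pd.DataFrame:
    """Run the test for every line of a counts CSV.

    Expects columns ``line_id, wt, het, hom``; returns a tidy results table
    (line_id, statistic, df, p_value).
    """
    df = pd.read_csv(path)
    rows = []
    for rec in df.itertuples(index=False):
        table = SegregationTable((int(rec.wt), int(rec.het), int(rec.hom)),
                                 tuple(ratio), line_id=str(rec.line_id))
        res = chisq_segregation(table)
        rows.append({"line_id": table.line_id, "statistic": res.statistic,
                     "df": res.df, "p_value": res.p_value})
    return pd.DataFrame(rows)
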