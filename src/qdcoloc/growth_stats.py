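"""Growth and gravitropism statistics.

The experimental unit is the plate: individual seedlings are pseudoreplicates
and are averaged by plate before any test.  On the plate-level table this
module provides

* one-way ANOVA across treatments with pairwise comparisons on the pooled
  error and Holm–Šidák step-down adjustment (Tukey HSD available as an
  alternative),
* two-way (genotype x treatment) ANOVA with Type II sums of squares and
  Šidák-adjusted wild-type-vs-mutant comparisons within each treatment,
* a linear-trend contrast across ordered dose groups (equally spaced integer
  coefficients by default; dose-value or log-dose coding optional) for
  gravitropism dose series.

Normality is assumed throughout; every reported p-value is a deterministic
function of the input table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["AnovaReport", "TrendResult", "average_pseudoreplicates",
           "one_way_anova", "two_way_anova", "linear_trend_contrast",
           "holm_sidak_adjust", "sidak_adjust"]


# ---------------------------------------------------------------------------
# p-value adjustments
# ---------------------------------------------------------------------------

def sidak_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Single-step Šidák: p_adj = 1 - (1 - p)^m, capped at 1."""
    p = np.asarray(p_raw, dtype=float)
    m = p.size
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


def holm_sidak_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Holm–Šidák step-down adjustment.

    Raw p-values are sorted ascending; the i-th smallest (1-based) is
    adjusted to 1 - (1 - p_(i))^(m - i + 1), then a running maximum enforces
    monotonicity.  Adjusted p's are never smaller than raw.
    """
    p = np.asarray(p_raw, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(1.0, np.maximum.accumulate(adj_sorted))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class AnovaReport:
    model: str                       # "one_way" | "two_way"
    anova_table: pd.DataFrame        # term, ss, df, F, p
    comparisons: pd.DataFrame        # group_a, group_b, [within], estimate, t, p_raw, p_adj
    group_stats: pd.DataFrame        # group, n, mean, se
    comparison_method: str
    residual_df: int
    mse: float

    def summary(self) -> str:
        lines = [f"{self.model} ANOVA ({self.comparison_method} comparisons)",
                 self.anova_table.to_string(index=False), "",
                 "Group means +/- SE:",
                 self.group_stats.to_string(index=False), "",
                 "Comparisons:",
                 self.comparisons.to_string(index=False)]
        return "\n".join(lines)


@dataclass
class TrendResult:
    coefficients: dict[str, float]
    estimate: float
    se: float
    t: float
    df: int
    p_value: float
    coding: str


# ---------------------------------------------------------------------------
# plate averaging
# ---------------------------------------------------------------------------

def average_pseudoreplicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average seedlings within each plate.

    One record per (plate, measure): the mean over that plate's seedlings,
    keeping the plate's treatment/genotype annotation.  Plates — not
    seedlings — are the replicates in every downstream test.
    """
    keys = [c for c in ("plate_id", "treatment", "genotype", "measure_name")
            if c in table.columns]
    if "plate_id" not in keys:
        raise ValueError("table must have a plate_id column")
    out = (table.groupby(keys, as_index=False, sort=False)["value"]
                .mean())
    return out


def _group_arrays(plate_table: pd.DataFrame, measure: str | None,
                  group_col: str) -> dict[str, np.ndarray]:
    df = plate_table
    if measure is not None and "measure_name" in df.columns:
        df = df[df["measure_name"] == measure]
        if df.empty:
            raise ValueError(f"no rows for measure {measure!r}")
    return {g: sub["value"].to_numpy(dtype=float)
            for g, sub in df.groupby(group_col, sort=False)}


def _anova_decomposition(groups: dict[str, np.ndarray]):
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return ss_between, ss_within, df_b, df_w


# ---------------------------------------------------------------------------
# one-way ANOVA + multiple comparisons
# ---------------------------------------------------------------------------

def one_way_anova(plate_table: pd.DataFrame,
                  measure: str | None = None,
                  group_col: str = "treatment",
                  comparisons: Sequence[tuple[str, str]] | None = None,
                  method: str = "holm_sidak") -> AnovaReport:
    """One-way ANOVA with pairwise comparisons on the pooled error.

    ``comparisons`` defaults to all pairs.  ``method`` is one of
    ``holm_sidak`` (default), ``sidak`` or ``tukey``.
    """
    groups = _group_arrays(plate_table, measure, group_col)
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 plates each")
    ss_b, ss_w, df_b, df_w = _anova_decomposition(groups)
    mse = ss_w / df_w
    F = (ss_b / df_b) / mse if mse > 0 else (np.inf if ss_b > 0 else 0.0)
    p_omni = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    if mse == 0 and ss_b == 0:
        F, p_omni = 0.0, 1.0

    anova_table = pd.DataFrame([
        {"term": group_col, "ss": ss_b, "df": df_b, "F": F, "p": p_omni},
        {"term": "residual", "ss": ss_w, "df": df_w, "F": np.nan, "p": np.nan},
    ])
    group_stats = pd.DataFrame(
        [{"group": g, "n": len(v), "mean": v.mean(),
          "se": np.sqrt(mse / len(v))} for g, v in groups.items()])

    pairs = list(comparisons) if comparisons is not None else \
        list(itertools.combinations(groups.keys(), 2))
    for a, b in pairs:
        for g in (a, b):
            if g not in groups:
                raise ValueError(f"comparison names absent group {g!r}; "
                                 f"available: {sorted(groups)}")

    if method == "tukey":
        df = plate_table
        if measure is not None and "measure_name" in df.columns:
            df = df[df["measure_name"] == measure]
        tk = pairwise_tukeyhsd(df["value"].to_numpy(dtype=float),
                               df[group_col].to_numpy())
        comp = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        comp = comp.rename(columns={"group1": "group_a", "group2": "group_b",
                                    "meandiff": "estimate", "p-adj": "p_adj"})
        comp["t"] = np.nan
        comp["p_raw"] = np.nan
        comp = comp[["group_a", "group_b", "estimate", "t", "p_raw", "p_adj"]]
    elif method in ("holm_sidak", "sidak"):
        rows = []
        for a, b in pairs:
            va, vb = groups[a], groups[b]
            est = va.mean() - vb.mean()
            se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
            t = est / se if se > 0 else (np.inf if est != 0 else 0.0)
            p = 2 * stats.t.sf(abs(t), df_w) if np.isfinite(t) else 0.0
            if se == 0 and est == 0:
                p = 1.0
            rows.append({"group_a": a, "group_b": b, "estimate": est,
                         "t": t, "p_raw": p})
        comp = pd.DataFrame(rows)
        adjust = holm_sidak_adjust if method == "holm_sidak" else sidak_adjust
        comp["p_adj"] = adjust(comp["p_raw"].to_numpy())
    else:
        raise ValueError(f"unknown comparison method: {method!r}")

    return AnovaReport("one_way", anova_table, comp, group_stats,
                       method, df_w, mse)


# ---------------------------------------------------------------------------
# two-way ANOVA + per-treatment genotype comparisons
# ---------------------------------------------------------------------------

def two_way_anova(plate_table: pd.DataFrame,
                  measure: str | None = None,
                  factors: tuple[str, str] = ("genotype", "treatment"),
                  comparison_factor: str = "genotype",
                  within: str = "treatment",
                  method: str = "sidak") -> AnovaReport:
    """Two-way factorial ANOVA (Type II SS) with within-treatment comparisons.

    The two levels of ``comparison_factor`` (e.g. wild type vs mutant) are
    compared inside each level of ``within`` using the full model's residual
    error; the per-comparison p-values are Šidák-adjusted over the number of
    ``within`` levels.
    """
    df = plate_table
    if measure is not None and "measure_name" in df.columns:
        df = df[df["measure_name"] == measure]
    f1, f2 = factors
    cells = df.groupby([f1, f2], sort=False)["value"].count()
    for (a, b) in itertools.product(df[f1].unique(), df[f2].unique()):
        n = cells.get((a, b), 0)
        if n < 2:
            raise ValueError(f"factorial cell ({f1}={a!r}, {f2}={b!r}) has "
                             f"{n} plates; every cell needs >= 2")

    data = df.rename(columns={"value": "y"})
    # a factor with one observed level drops out of the model (the design
    # degenerates to one-way); the full crossed model is used otherwise
    active = [f for f in (f1, f2) if data[f].nunique() > 1]
    if not active:
        raise ValueError("both factors have a single level; nothing to test")
    rhs = f"C({active[0]}) * C({active[1]})" if len(active) == 2 \
        else f"C({active[0]})"
    model = smf.ols(f"y ~ {rhs}", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    anova_table = pd.DataFrame({
        "term": [t.replace("C(", "").replace(")", "") for t in aov.index],
        "ss": aov["sum_sq"].to_numpy(),
        "df": aov["df"].to_numpy(),
        "F": aov["F"].to_numpy(),
        "p": aov["PR(>F)"].to_numpy(),
    })
    mse = float(model.mse_resid)
    df_resid = int(model.df_resid)

    levels = list(df[comparison_factor].unique())
    if len(levels) != 2:
        raise ValueError(f"{comparison_factor} must have exactly 2 levels "
                         f"for within-{within} comparisons; got {levels}")
    ref, alt = levels
    rows = []
    for t_level, sub in df.groupby(within, sort=False):
        va = sub.loc[sub[comparison_factor] == ref, "value"].to_numpy(dtype=float)
        vb = sub.loc[sub[comparison_factor] == alt, "value"].to_numpy(dtype=float)
        est = va.mean() - vb.mean()
        se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
        t = est / se if se > 0 else (np.inf if est != 0 else 0.0)
        p = 2 * stats.t.sf(abs(t), df_resid) if np.isfinite(t) else 0.0
        if se == 0 and est == 0:
            p = 1.0
        rows.append({"group_a": ref, "group_b": alt, "within": t_level,
                     "estimate": est, "t": t, "p_raw": p})
    comp = pd.DataFrame(rows)
    comp["p_adj"] = sidak_adjust(comp["p_raw"].to_numpy())

    group_stats = (df.groupby([f1, f2])["value"]
                     .agg(n="count", mean="mean")
                     .reset_index())
    group_stats["se"] = np.sqrt(mse / group_stats["n"])
    group_stats["group"] = group_stats[f1].astype(str) + "/" + group_stats[f2].astype(str)
    group_stats = group_stats[["group", "n", "mean", "se"]]

    return AnovaReport("two_way", anova_table, comp, group_stats,
                       method, df_resid, mse)


# ---------------------------------------------------------------------------
# linear-trend (dose-response) contrast
# ---------------------------------------------------------------------------

def linear_trend_contrast(plate_table: pd.DataFrame,
                          ordered_groups: Sequence[str],
                          measure: str | None = None,
                          group_col: str = "treatment",
                          coding: str = "rank",
                          dose_values: Sequence[float] | None = None) -> TrendResult:
    """Linear contrast across ordered dose groups over the ANOVA pooled error.

    ``rank`` coding (default) uses equally spaced integer coefficients
    centred at zero (e.g. -1, 0, 1 or -3, -1, 1, 3); ``value``/``log``
    coding centres the (log-)doses themselves, for which ``dose_values``
    must be given.  Two-sided p from the t distribution on the within-group
    degrees of freedom.
    """
    if len(ordered_groups) < 3:
        raise ValueError("linear trend needs >= 3 ordered groups")
    groups_all = _group_arrays(plate_table, measure, group_col)
    missing = [g for g in ordered_groups if g not in groups_all]
    if missing:
        raise ValueError(f"groups absent from table: {missing}")
    groups = {g: groups_all[g] for g in ordered_groups}

    k = len(ordered_groups)
    if coding == "rank":
        c = np.arange(k, dtype=float) - (k - 1) / 2.0
        if k % 2 == 0:          # make coefficients integer
            c = 2 * c
    elif coding in ("value", "log"):
        if dose_values is None or len(dose_values) != k:
            raise ValueError(f"coding={coding!r} requires one dose value per group")
        d = np.asarray(dose_values, dtype=float)
        if coding == "log":
            if (d <= 0).any():
                raise ValueError("log coding requires positive doses")
            d = np.log(d)
        c = d - d.mean()
    else:
        raise ValueError(f"unknown coding: {coding!r}")

    _, ss_w, _, df_w = _anova_decomposition(groups)
    mse = ss_w / df_w
    means = np.array([v.mean() for v in groups.values()])
    ns = np.array([len(v) for v in groups.values()])
    est = float(c @ means)
    se = float(np.sqrt(mse * np.sum(c ** 2 / ns)))
    t = est / se if se > 0 else (np.inf if est != 0 else 0.0)
    p = float(2 * stats.t.sf(abs(t), df_w)) if np.isfinite(t) else 0.0
    if se == 0 and est == 0:
        t, p = 0.0, 1.0
    return TrendResult(dict(zip(ordered_groups, c)), est, se, float(t),
                       df_w, p, coding)
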