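"""Statistics for placebo-controlled CBC intervention panels.

Panels are long-format tables with columns ``subject_id, group, time_days,
analyte, value``; negative ``time_days`` are baseline samples.  The module
provides subject-level baseline correction and fractional change, pooled or
per-subject correlations, Welch and paired t tests, Benjamini–Hochberg
adjustment, and per-timepoint treated-vs-placebo contrasts on
baseline-corrected values with BH across timepoints.

The per-timepoint contrast analysis is a deliberate simplification of a
linear mixed-effects model with subject random intercepts: subtracting each
subject's mean baseline absorbs the random intercept, after which a Welch
test per post-baseline timepoint (BH-adjusted across timepoints) answers
the same per-timepoint question without REML machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "TestResult",
    "baseline_correct",
    "fractional_change",
    "correlate",
    "welch_t_summary",
    "paired_t",
    "bh_adjust",
    "per_timepoint_contrasts",
]

_PANEL_COLUMNS = ("subject_id", "group", "time_days", "analyte", "value")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str
    scope: str


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    estimate: float
    ci95: tuple


def _check_panel(panel: pd.DataFrame) -> None:
    missing = [c for c in _PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel lacks columns {missing}")
    dup = panel.duplicated(subset=["subject_id", "time_days", "analyte"])
    if dup.any():
        raise ValueError("(subject, time, analyte) rows must be unique")


def _baseline_means(panel: pd.DataFrame) -> pd.Series:
    """Per (subject, analyte) mean of baseline (time < 0) values."""
    base = panel[panel["time_days"] < 0]
    means = base.groupby(["subject_id", "analyte"])["value"].mean()
    all_keys = panel.groupby(["subject_id", "analyte"]).size().index
    lacking = sorted(set(all_keys) - set(means.index))
    if lacking:
        raise ValueError(f"subjects lacking baseline records: {lacking}")
    return means


def baseline_correct(panel: pd.DataFrame) -> pd.DataFrame:
    """Subtract each subject's mean baseline per analyte.

    Post-baseline values become ``value − mean(baseline)``; baseline rows are
    retained with their own correction applied (so a noiseless placebo
    subject reads exactly 0 throughout), and the subtracted baseline mean is
    kept in a ``baseline_mean`` audit column.
    """
    _check_panel(panel)
    means = _baseline_means(panel)
    out = panel.copy()
    keys = pd.MultiIndex.from_frame(out[["subject_id", "analyte"]])
    bl = means.reindex(keys).to_numpy()
    out["baseline_mean"] = bl
    out["value"] = out["value"] - bl
    return out


def fractional_change(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-subject fractional change: value / mean(baseline) − 1."""
    _check_panel(panel)
    means = _baseline_means(panel)
    if (means == 0).any():
        bad = means[means == 0].index.tolist()
        raise ValueError(f"zero baseline mean for {bad}")
    out = panel.copy()
    keys = pd.MultiIndex.from_frame(out[["subject_id", "analyte"]])
    bl = means.reindex(keys).to_numpy()
    out["baseline_mean"] = bl
    out["value"] = out["value"] / bl - 1.0
    return out


def correlate(
    panel: pd.DataFrame,
    analyte_x: str,
    analyte_y: str,
    method: str = "pearson",
    scope: str = "pooled",
) -> CorrelationResult:
    """Correlation between two analytes across (subject, time) samples.

    ``pooled`` pairs every (subject, time) sample that has both analytes and
    computes one correlation; ``per_subject`` computes the within-subject
    correlation and reports its mean across subjects (p from a one-sample t
    test of the Fisher-z transformed per-subject coefficients against 0).
    """
    _check_panel(panel)
    wide = panel.pivot_table(
        index=["subject_id", "time_days"], columns="analyte", values="value"
    )
    for a in (analyte_x, analyte_y):
        if a not in wide.columns:
            raise ValueError(f"analyte {a!r} absent from panel")
    pairs = wide[[analyte_x, analyte_y]].dropna()

    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")

    if scope == "pooled":
        if len(pairs) < 3:
            raise ValueError("need >= 3 complete pairs")
        res = corr_fn(pairs[analyte_x], pairs[analyte_y])
        return CorrelationResult(
            r=float(res.statistic), p=float(res.pvalue), n=len(pairs),
            method=method, scope=scope,
        )
    if scope == "per_subject":
        rs = []
        for _, sub in pairs.groupby(level="subject_id"):
            if len(sub) >= 3 and sub[analyte_x].nunique() > 1 and sub[analyte_y].nunique() > 1:
                rs.append(float(corr_fn(sub[analyte_x], sub[analyte_y]).statistic))
        if len(rs) < 2:
            raise ValueError("need >= 2 subjects with >= 3 complete pairs each")
        z = np.arctanh(np.clip(rs, -0.999999, 0.999999))
        t_res = stats.ttest_1samp(z, 0.0)
        return CorrelationResult(
            r=float(np.mean(rs)), p=float(t_res.pvalue), n=len(rs),
            method=method, scope=scope,
        )
    raise ValueError(f"unknown scope {scope!r}")


def welch_t_summary(m1, s1, n1, m2, s2, n2) -> TestResult:
    """Two-sided Welch t test from group summaries (mean, SD, n).

    Uses the unequal-variance statistic with Welch–Satterthwaite degrees of
    freedom; the effect estimate is m1 − m2 with a t-based 95% CI.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("SDs must be positive")
    t_stat, p = stats.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=False
    )
    se2_1, se2_2 = s1**2 / n1, s2**2 / n2
    df = (se2_1 + se2_2) ** 2 / (
        se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
    )
    se = np.sqrt(se2_1 + se2_2)
    tq = stats.t.ppf(0.975, df)
    est = m1 - m2
    return TestResult(
        statistic=float(t_stat), df=float(df), p=float(p),
        estimate=float(est), ci95=(float(est - tq * se), float(est + tq * se)),
    )


def paired_t(values_a, values_b, keys_a=None, keys_b=None) -> TestResult:
    """Two-sided paired t test, optionally matching observations by keys."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if keys_a is not None or keys_b is not None:
        sa = pd.Series(a, index=pd.Index(keys_a))
        sb = pd.Series(b, index=pd.Index(keys_b))
        unmatched = sorted(set(sa.index) ^ set(sb.index))
        if unmatched:
            raise ValueError(f"unmatched pairing keys: {unmatched}")
        sb = sb.reindex(sa.index)
        a, b = sa.to_numpy(), sb.to_numpy()
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need >= 2 complete pairs")
    diff = a - b
    if np.ptp(diff) == 0:
        if diff[0] != 0:
            raise ValueError("constant nonzero differences: t statistic undefined")
        # identical vectors: no evidence of a shift
        return TestResult(statistic=0.0, df=float(a.size - 1), p=1.0,
                          estimate=0.0, ci95=(0.0, 0.0))
    res = stats.ttest_rel(a, b)
    n = a.size
    se = diff.std(ddof=1) / np.sqrt(n)
    est = float(diff.mean())
    tq = stats.t.ppf(0.975, n - 1)
    ci = (est - tq * se, est + tq * se) if se > 0 else (est, est)
    return TestResult(
        statistic=float(res.statistic), df=float(n - 1), p=float(res.pvalue),
        estimate=est, ci95=(float(ci[0]), float(ci[1])),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("pvalues must be non-empty")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def per_timepoint_contrasts(
    panel: pd.DataFrame, analyte: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Treated-vs-placebo Welch contrasts per post-baseline timepoint.

    Values are baseline-corrected first; at each post-baseline timepoint with
    both groups present (>= 2 subjects each) a Welch test compares treated
    against placebo, and BH adjustment is applied across timepoints.
    Timepoints missing a group are skipped with a warning column rather than
    an exception.
    """
    _check_panel(panel)
    corrected = baseline_correct(panel)
    sub = corrected[(corrected["analyte"] == analyte) & (corrected["time_days"] >= 0)]
    if sub.empty:
        raise ValueError(f"no post-baseline rows for analyte {analyte!r}")
    rows = []
    for t, grp in sub.groupby("time_days"):
        treated = grp.loc[grp["group"] == "treated", "value"].to_numpy()
        placebo = grp.loc[grp["group"] == "placebo", "value"].to_numpy()
        if treated.size < 2 or placebo.size < 2:
            import warnings

            warnings.warn(f"timepoint {t} lacks a full group; skipped", stacklevel=2)
            continue
        if treated.std(ddof=1) == 0 and placebo.std(ddof=1) == 0:
            # degenerate zero-noise case: identical groups → p = 1
            equal = treated.mean() == placebo.mean()
            rows.append(
                {
                    "time_days": t, "statistic": 0.0 if equal else np.inf,
                    "df": float(treated.size + placebo.size - 2),
                    "p": 1.0 if equal else 0.0,
                    "estimate": float(treated.mean() - placebo.mean()),
                    "n_treated": treated.size, "n_placebo": placebo.size,
                }
            )
            continue
        res = welch_t_summary(
            treated.mean(), treated.std(ddof=1), treated.size,
            placebo.mean(), placebo.std(ddof=1), placebo.size,
        )
        rows.append(
            {
                "time_days": t, "statistic": res.statistic, "df": res.df,
                "p": res.p, "estimate": res.estimate,
                "n_treated": treated.size, "n_placebo": placebo.size,
            }
        )
    table = pd.DataFrame(rows).sort_values("time_days").reset_index(drop=True)
    if table.empty:
        raise ValueError("no timepoint had both groups present")
    table["p_adj"] = bh_adjust(table["p"].clip(lower=np.nextafter(0, 1)))
    table["significant"] = table["p_adj"] < alpha
    return table
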