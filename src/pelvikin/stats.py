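"""Agreement and between-condition statistics.

Implements the method-comparison layer: normality-gated bias tests (paired t
or Wilcoxon signed-rank), two-way mixed-effects intraclass correlation for
average measures in both the consistency and absolute-agreement forms with
F-based 95% confidence bounds, CI-lower-bound agreement categories,
Bland-Altman bias and limits of agreement with a proportional-bias slope, and
the between-task (repeated-measures ANOVA with Greenhouse-Geisser correction,
or Friedman) and between-group (independent t or rank-sum) comparisons with
Bonferroni-corrected post hocs.

ICC formulas (n participants, k raters; MSR/MSC/MSE the row, column and
residual mean squares of the two-way layout):

* consistency, average measures:        (MSR - MSE) / MSR
* absolute agreement, average measures: (MSR - MSE) / (MSR + (MSC - MSE)/n)

The consistency CI uses the exact F bounds on MSR/MSE; the absolute-agreement
CI uses the Satterthwaite-degrees-of-freedom F approximation on the
single-measures form, transformed to average measures by Spearman-Brown.
Differences are oriented motion-capture minus smartphone throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import TaskLabel

BIAS_ALPHA = 0.05

#: outcome column -> unit, defining the agreement-report rows (x 3 tasks = 15)
OUTCOME_UNITS = {
    "transverse": "deg",
    "frontal": "deg",
    "sagittal": "deg",
    "ml_acceleration": "m/s^2",
    "duration": "s",
}


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    return min(1.0, m * p)


# ---------------------------------------------------------------------------
# bias
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiasTestResult:
    test: str  # "paired_t" | "wilcoxon" | "degenerate"
    statistic: float | None
    p: float | None
    mean_difference: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p is not None and self.p < BIAS_ALPHA


def test_bias(
    mocap: np.ndarray, phone: np.ndarray, alpha: float = 0.05
) -> BiasTestResult:
    """Systematic-difference test on paired values (differences mocap - phone).

    A Shapiro-Wilk test on the differences gates the choice: normal at
    ``alpha`` uses the two-tailed paired t test, otherwise the Wilcoxon
    signed-rank test (zero differences dropped).  All-equal differences make
    the test degenerate (bias reported, no p).
    """
    mocap = np.asarray(mocap, dtype=float)
    phone = np.asarray(phone, dtype=float)
    if mocap.shape != phone.shape or mocap.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    n = mocap.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    diffs = mocap - phone
    if np.ptp(diffs) == 0.0:
        return BiasTestResult("degenerate", None, None, float(diffs.mean()), n)
    if sps.shapiro(diffs).pvalue > alpha:
        res = sps.ttest_rel(mocap, phone)
        return BiasTestResult(
            "paired_t", float(res.statistic), float(res.pvalue), float(diffs.mean()), n
        )
    res = sps.wilcoxon(diffs, zero_method="wilcox")
    return BiasTestResult(
        "wilcoxon", float(res.statistic), float(res.pvalue), float(diffs.mean()), n
    )


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    model: str  # "consistency" | "absolute"
    estimate: float | None
    ci95: tuple[float, float] | None
    category: str | None
    n: int
    k: int
    degenerate: bool = False


def classify_icc(ci_lower: float) -> str:
    """Agreement category from the lower 95% CI bound.

    poor < 0.5 <= moderate < 0.75 <= good <= 0.9 < excellent.
    """
    if not -1.0 <= ci_lower <= 1.0:
        raise ValueError(f"CI lower bound {ci_lower} outside [-1, 1]")
    if ci_lower < 0.5:
        return "poor"
    if ci_lower < 0.75:
        return "moderate"
    if ci_lower <= 0.9:
        return "good"
    return "excellent"


def _mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    """Row, column and residual mean squares of a complete two-way layout."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((table - grand) ** 2))
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_average(
    table: np.ndarray, model: str = "absolute", confidence: float = 0.95
) -> ICCResult:
    """Two-way mixed-effects ICC for average measures with a 95% CI.

    ``table`` is (n participants, k raters); here k = 2 (the two measurement
    systems).  ``model`` selects the consistency or absolute-agreement form.
    Zero between-participant variance makes the ICC undefined (degenerate
    result).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("table must be (n, k) with k >= 2")
    n, k = table.shape
    if n < 3:
        raise ValueError(f"need at least 3 participants, got {n}")
    if model not in ("consistency", "absolute"):
        raise ValueError(f"unknown ICC model {model!r}")

    msr, msc, mse = _mean_squares(table)
    if msr <= 0.0:
        return ICCResult(model, None, None, None, n, k, degenerate=True)

    q = 1.0 - (1.0 - confidence) / 2.0
    df_rows = n - 1
    df_err = (n - 1) * (k - 1)

    if model == "consistency":
        estimate = (msr - mse) / msr
        if mse == 0.0:
            lower = upper = 1.0
        else:
            f_obs = msr / mse
            fl = f_obs / sps.f.ppf(q, df_rows, df_err)
            fu = f_obs * sps.f.ppf(q, df_err, df_rows)
            lower = 1.0 - 1.0 / fl
            upper = 1.0 - 1.0 / fu
    else:
        denom = msr + (msc - mse) / n
        estimate = (msr - mse) / denom if denom > 0 else None
        if estimate is None:
            return ICCResult(model, None, None, None, n, k, degenerate=True)
        if mse == 0.0 and msc <= mse:
            lower = upper = 1.0
        else:
            # single-measures form, Satterthwaite df, then Spearman-Brown
            r1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
            a = k * r1 / (n * (1.0 - r1)) if r1 < 1.0 else np.inf
            b = 1.0 + k * r1 * (n - 1) / (n * (1.0 - r1)) if r1 < 1.0 else np.inf
            if np.isinf(a) or np.isinf(b):
                lower = upper = 1.0
            else:
                num = (a * msc + b * mse) ** 2
                den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / df_err
                v = num / den if den > 0 else df_err
                f1 = sps.f.ppf(q, df_rows, v)
                f2 = sps.f.ppf(q, v, df_rows)
                lo1 = (
                    n * (msr - f1 * mse)
                    / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
                )
                up1 = (
                    n * (f2 * msr - mse)
                    / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
                )
                lower = k * lo1 / (1.0 + (k - 1) * lo1)
                upper = k * up1 / (1.0 + (k - 1) * up1)

    lower = float(np.clip(lower, -1.0, 1.0))
    upper = float(np.clip(upper, -1.0, 1.0))
    category = classify_icc(lower)
    return ICCResult(model, float(estimate), (lower, upper), category, n, k)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    slope: float
    slope_p: float | None
    n: int


def bland_altman(mocap: np.ndarray, phone: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement (mocap - phone).

    Limits are bias +/- 1.96 x sample SD of the differences.  The slope of
    the regression of difference on pair mean quantifies proportional bias.
    """
    mocap = np.asarray(mocap, dtype=float)
    phone = np.asarray(phone, dtype=float)
    if mocap.shape != phone.shape or mocap.ndim != 1 or mocap.shape[0] < 3:
        raise ValueError("need >= 3 equal-length pairs")
    diffs = mocap - phone
    means = 0.5 * (mocap + phone)
    bias = float(diffs.mean())
    sd = float(np.std(diffs, ddof=1))
    if np.ptp(means) > 0:
        reg = sps.linregress(means, diffs)
        slope, slope_p = float(reg.slope), float(reg.pvalue)
    else:
        slope, slope_p = 0.0, None
    return BlandAltmanResult(
        bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, slope, slope_p, mocap.shape[0]
    )


# ---------------------------------------------------------------------------
# between-task and between-group comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PosthocRow:
    pair: tuple[str, str]
    test: str
    statistic: float | None
    p_raw: float | None
    p_adjusted: float | None
    mean_difference: float  # second minus first

    @property
    def significant(self) -> bool:
        return self.p_adjusted is not None and self.p_adjusted < 0.05


@dataclass
class ComparisonResult:
    test: str  # "rm_anova" | "friedman" | "degenerate"
    statistic: float | None
    df: tuple[float, float] | None
    p: float | None
    n: int
    n_dropped: int
    sphericity: dict | None = None
    posthoc: list[PosthocRow] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p is not None and self.p < 0.05


def friedman_statistic(wide: pd.DataFrame) -> tuple[float, float]:
    """Friedman chi-square statistic and p over the columns of ``wide``."""
    cols = [wide[c].to_numpy(dtype=float) for c in wide.columns]
    res = sps.friedmanchisquare(*cols)
    return float(res.statistic), float(res.pvalue)


def _paired_posthoc(
    wide: pd.DataFrame, alpha: float, m: int
) -> list[PosthocRow]:
    rows: list[PosthocRow] = []
    cols = list(wide.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a = wide[cols[i]].to_numpy(dtype=float)
            b = wide[cols[j]].to_numpy(dtype=float)
            res = test_bias(b, a, alpha)  # differences oriented second - first
            rows.append(
                PosthocRow(
                    pair=(str(cols[i]), str(cols[j])),
                    test=res.test,
                    statistic=res.statistic,
                    p_raw=res.p,
                    p_adjusted=None if res.p is None else bonferroni(res.p, m),
                    mean_difference=res.mean_difference,
                )
            )
    return rows


def compare_tasks(
    wide: pd.DataFrame,
    alpha: float = 0.05,
    method: str | None = None,
    posthoc_when_significant: bool = True,
) -> ComparisonResult:
    """Between-task comparison of one outcome (columns = tasks, rows = participants).

    Incomplete cases are dropped (and counted).  A Shapiro-Wilk gate on every
    task column selects repeated-measures ANOVA (all normal) or the Friedman
    test; the ANOVA applies the Greenhouse-Geisser correction to the degrees
    of freedom when Mauchly's test rejects sphericity at ``alpha``.  A
    significant overall test triggers the 3 pairwise gated post hocs with
    Bonferroni m = 3.  ``method`` forces ``"rm_anova"`` or ``"friedman"``.
    """
    complete = wide.dropna()
    n_dropped = wide.shape[0] - complete.shape[0]
    n = complete.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 complete cases, got {n}")
    k = complete.shape[1]
    values = complete.to_numpy(dtype=float)
    if np.ptp(values) == 0.0:
        return ComparisonResult("degenerate", None, None, None, n, n_dropped)

    if method is None:
        normal = True
        for c in complete.columns:
            col = complete[c].to_numpy(dtype=float)
            if np.ptp(col) == 0.0 or sps.shapiro(col).pvalue <= alpha:
                normal = False
                break
        method = "rm_anova" if normal else "friedman"

    sphericity_info = None
    if method == "rm_anova":
        import pingouin as pg

        long = complete.reset_index(names="subject").melt(
            id_vars="subject", var_name="task", value_name="value"
        )
        aov = pg.rm_anova(
            data=long, dv="value", within="task", subject="subject", correction=True
        )
        row = aov.iloc[0]
        eps = float(row.get("eps", 1.0))
        spher_ok = bool(row.get("sphericity", True))
        ddof1, ddof2 = float(row["ddof1"]), float(row["ddof2"])
        if not spher_ok:
            p = float(row["p_GG_corr"])
            df = (ddof1 * eps, ddof2 * eps)
        else:
            p = float(row["p_unc"])
            df = (ddof1, ddof2)
        statistic = float(row["F"])
        sphericity_info = {
            "mauchly_ok": spher_ok,
            "epsilon": eps,
            "W": float(row["W_spher"]) if "W_spher" in row else None,
            "p_mauchly": float(row["p_spher"]) if "p_spher" in row else None,
        }
        result = ComparisonResult("rm_anova", statistic, df, p, n, n_dropped,
                                  sphericity=sphericity_info)
    elif method == "friedman":
        statistic, p = friedman_statistic(complete)
        result = ComparisonResult(
            "friedman", statistic, (float(k - 1), np.nan), p, n, n_dropped
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    if posthoc_when_significant and result.significant:
        m = k * (k - 1) // 2
        result.posthoc = _paired_posthoc(complete, alpha, m)
    return result


@dataclass(frozen=True)
class GroupComparisonResult:
    test: str  # "independent_t" | "rank_sum" | "degenerate"
    statistic: float | None
    p: float | None
    group_means: dict[str, float]
    n: dict[str, int]


def compare_groups(
    values: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> GroupComparisonResult:
    """Two-group comparison (e.g. genders) with a normality gate.

    Both groups normal by Shapiro-Wilk at ``alpha``: two-tailed independent t
    test; otherwise the Wilcoxon rank-sum (Mann-Whitney) test.  Constant and
    equal groups are degenerate (no p).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    g1 = values[labels == uniq[0]]
    g2 = values[labels == uniq[1]]
    if min(g1.shape[0], g2.shape[0]) < 3:
        raise ValueError("each group needs at least 3 values")
    means = {str(uniq[0]): float(g1.mean()), str(uniq[1]): float(g2.mean())}
    ns = {str(uniq[0]): int(g1.shape[0]), str(uniq[1]): int(g2.shape[0])}
    if np.ptp(g1) == 0.0 and np.ptp(g2) == 0.0:
        return GroupComparisonResult("degenerate", None, None, means, ns)
    normal = (
        np.ptp(g1) > 0.0
        and np.ptp(g2) > 0.0
        and sps.shapiro(g1).pvalue > alpha
        and sps.shapiro(g2).pvalue > alpha
    )
    if normal:
        res = sps.ttest_ind(g1, g2)
        return GroupComparisonResult(
            "independent_t", float(res.statistic), float(res.pvalue), means, ns
        )
    res = sps.mannwhitneyu(g1, g2, alternative="two-sided")
    return GroupComparisonResult(
        "rank_sum", float(res.statistic), float(res.pvalue), means, ns
    )


# ---------------------------------------------------------------------------
# agreement report (Table-1 analogue)
# ---------------------------------------------------------------------------


@dataclass
class AgreementRow:
    outcome: str
    task: TaskLabel
    unit: str
    n: int
    n_excluded: int
    computable: bool
    bias: BiasTestResult | None = None
    icc: ICCResult | None = None
    bland_altman: BlandAltmanResult | None = None


def build_agreement_report(
    task_outcomes: pd.DataFrame,
    alpha: float = 0.05,
    icc_model: str = "auto",
) -> list[AgreementRow]:
    """Per-outcome x task agreement analysis of a paired outcome table.

    ``task_outcomes`` is long format with columns ``participant``, ``task``,
    ``source`` and the five outcome columns of :data:`OUTCOME_UNITS`, plus a
    boolean ``drift_excluded`` marking recordings that failed the
    transverse-plane drift QC.  Returns 15 rows (3 planes + acceleration +
    duration, x 3 tasks); drift-flagged participants are excluded from the
    transverse rows only, with the exclusion count reported.  The ICC model
    follows the bias gate (significant bias -> consistency, otherwise
    absolute agreement) unless forced via ``icc_model``.
    """
    required = {"participant", "task", "source"} | set(OUTCOME_UNITS)
    missing = required - set(task_outcomes.columns)
    if missing:
        raise ValueError(f"outcome table missing columns: {sorted(missing)}")
    if "drift_excluded" not in task_outcomes.columns:
        task_outcomes = task_outcomes.assign(drift_excluded=False)

    rows: list[AgreementRow] = []
    tasks = [TaskLabel(t) for t in ("SLS", "SD15", "SD20")
             if t in set(str(x) for x in task_outcomes["task"])]
    for outcome, unit in OUTCOME_UNITS.items():
        for task in tasks:
            sub = task_outcomes[task_outcomes["task"].astype(str) == task.value]
            excluded = 0
            if outcome == "transverse":
                flagged = set(
                    sub.loc[sub["drift_excluded"].astype(bool), "participant"]
                )
                excluded = len(flagged)
                sub = sub[~sub["participant"].isin(flagged)]
            pivot = sub.pivot(index="participant", columns="source", values=outcome)
            pivot = pivot.dropna()
            n = pivot.shape[0]
            if n < 3 or "mocap" not in pivot.columns or "phone" not in pivot.columns:
                rows.append(
                    AgreementRow(outcome, task, unit, n, excluded, computable=False)
                )
                continue
            mocap = pivot["mocap"].to_numpy(dtype=float)
            phone = pivot["phone"].to_numpy(dtype=float)
            bias = test_bias(mocap, phone, alpha)
            if icc_model == "auto":
                model = "consistency" if bias.significant else "absolute"
            else:
                model = icc_model
            icc = icc_average(np.column_stack([mocap, phone]), model=model)
            ba = bland_altman(mocap, phone)
            rows.append(
                AgreementRow(outcome, task, unit, n, excluded, True, bias, icc, ba)
            )
    return rows


def agreement_report_frame(rows: list[AgreementRow]) -> pd.DataFrame:
    """Flatten agreement rows into a tidy table."""
    records = []
    for r in rows:
        rec = {
            "outcome": r.outcome,
            "task": r.task.value,
            "unit": r.unit,
            "n": r.n,
            "n_excluded": r.n_excluded,
            "computable": r.computable,
        }
        if r.computable:
            rec.update(
                {
                    "bias_test": r.bias.test,
                    "bias": r.bias.mean_difference,
                    "bias_statistic": r.bias.statistic,
                    "bias_p": r.bias.p,
                    "icc_model": r.icc.model,
                    "icc": r.icc.estimate,
                    "icc_ci_lower": None if r.icc.ci95 is None else r.icc.ci95[0],
                    "icc_ci_upper": None if r.icc.ci95 is None else r.icc.ci95[1],
                    "icc_category": r.icc.category,
                    "ba_bias": r.bland_altman.bias,
                    "ba_loa_lower": r.bland_altman.loa_lower,
                    "ba_loa_upper": r.bland_altman.loa_upper,
                    "ba_slope": r.bland_altman.slope,
                }
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)
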