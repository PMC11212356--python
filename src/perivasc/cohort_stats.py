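"""Cohort statistics: normality-gated tests, fold changes, ANOVA, correlations.

The comparison workflow mirrors common practice in exploratory clinical
imaging cohorts:

* each sample is screened with both the D'Agostino–Pearson omnibus test and
  the Shapiro–Wilk test at alpha = 0.05; passing **either** test counts as
  Gaussian (the gate is deliberately permissive);
* two-group contrasts use the pooled-variance unpaired two-tailed Student's
  t test when both groups pass the gate, and the two-tailed Mann–Whitney U
  test otherwise;
* within-subject arteriole-vs-venule contrasts use the paired two-tailed t;
* group contrasts are reported with the fold change of means and a Fieller
  95% confidence interval for the ratio;
* three-level severity stratifications use one-way ANOVA with Tukey's HSD;
* count-vs-clinical associations use Pearson's r on pairwise-complete
  observations, with Holm–Bonferroni correction applied within each family
  of comparisons (default family: one clinical variable's column).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GATE_ALPHA = 0.05

# D'Agostino-Pearson needs at least 8 observations for its kurtosis component.
_DAGOSTINO_MIN_N = 8


class StatsError(ValueError):
    pass


@dataclass
class StatResult:
    variable: str
    groups: tuple[str, str]
    test_used: str                  # paired_t | unpaired_t | mann_whitney | anova_tukey
    statistic: float
    df: float | None
    p_two_tailed: float
    n: tuple[int, int]
    fold_change: float | None = None
    fc_ci95: tuple[float, float] | None = None
    mean_difference: float | None = None


@dataclass
class CorrelationCell:
    vascular_category: str
    clinical_variable: str
    r: float
    p: float
    n: int
    holm_significant: bool


def _clean(sample) -> np.ndarray:
    x = np.asarray(sample, dtype=float)
    return x[~np.isnan(x)]


def gaussian_gate(sample, alpha: float = GATE_ALPHA) -> str:
    """Classify a sample as ``"gaussian"`` or ``"non_gaussian"``.

    Runs the D'Agostino–Pearson and Shapiro–Wilk tests; the sample is
    Gaussian if at least one p-value exceeds ``alpha``.  When a test is
    inapplicable (sample too small for the omnibus test) the decision rests
    on the remaining test alone.
    """
    x = _clean(sample)
    if len(x) < 3:
        raise StatsError(f"need >= 3 observations for normality testing, got {len(x)}")
    if np.ptp(x) == 0:
        return "gaussian"  # degenerate constant sample; t test handles it downstream
    ps = []
    if len(x) >= _DAGOSTINO_MIN_N:
        ps.append(stats.normaltest(x).pvalue)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ps.append(stats.shapiro(x).pvalue)
    return "gaussian" if any(p > alpha for p in ps) else "non_gaussian"


def paired_vessel_comparison(
    peri_a_counts, peri_v_counts, variable: str = "AP_count"
) -> StatResult:
    """Paired two-tailed t test of per-subject arteriolar vs venular counts."""
    a, v = np.asarray(peri_a_counts, float), np.asarray(peri_v_counts, float)
    if a.shape != v.shape:
        raise StatsError("paired samples must be aligned")
    keep = ~(np.isnan(a) | np.isnan(v))
    a, v = a[keep], v[keep]
    if len(a) < 3:
        raise StatsError("need >= 3 complete pairs")
    diffs = a - v
    if np.all(diffs == diffs[0]) and diffs[0] == 0:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(a, v)
    return StatResult(
        variable=variable,
        groups=("peri_arteriolar", "peri_venular"),
        test_used="paired_t",
        statistic=float(t),
        df=float(len(a) - 1),
        p_two_tailed=float(p),
        n=(len(a), len(v)),
        mean_difference=float(np.mean(diffs)),
    )


def fold_change(
    mean_ref: float, sd_ref: float, n_ref: int,
    mean_cmp: float, sd_cmp: float, n_cmp: int,
    conf: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Fold change of means (cmp / ref) with a Fieller confidence interval.

    Fieller's theorem gives an exact interval for the ratio of two
    independent normal means.  When the reference mean is too noisy
    (its CI includes zero, g >= 1) the interval is unbounded and reported as
    (nan, nan).
    """
    if mean_ref <= 0:
        raise StatsError("fold change undefined for non-positive reference mean")
    fc = mean_cmp / mean_ref
    se_ref2 = sd_ref**2 / n_ref
    se_cmp2 = sd_cmp**2 / n_cmp
    df = n_ref + n_cmp - 2
    tcrit = stats.t.ppf(0.5 + conf / 2, df)
    g = tcrit**2 * se_ref2 / mean_ref**2
    if g >= 1:
        return fc, (float("nan"), float("nan"))
    disc = se_cmp2 + fc**2 * se_ref2 - g * se_cmp2
    half = (tcrit / mean_ref) * math.sqrt(disc)
    lo = (fc - half) / (1 - g)
    hi = (fc + half) / (1 - g)
    return fc, (lo, hi)


def fold_change_bootstrap(
    x_ref, x_cmp, conf: float = 0.95, n_boot: int = 2000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Percentile-bootstrap alternative CI for the ratio of means."""
    rng = np.random.default_rng(seed)
    x_ref, x_cmp = _clean(x_ref), _clean(x_cmp)
    fc = x_cmp.mean() / x_ref.mean()
    ratios = []
    for _ in range(n_boot):
        r = rng.choice(x_ref, len(x_ref)).mean()
        c = rng.choice(x_cmp, len(x_cmp)).mean()
        if r > 0:
            ratios.append(c / r)
    lo, hi = np.percentile(ratios, [(1 - conf) / 2 * 100, (1 + conf) / 2 * 100])
    return fc, (float(lo), float(hi))


def group_comparison_from_stats(
    mean_x: float, sd_x: float, n_x: int,
    mean_y: float, sd_y: float, n_y: int,
    variable: str = "", groups: tuple[str, str] = ("x", "y"),
) -> StatResult:
    """Pooled-variance two-tailed t from printed summary statistics.

    Lets table cells reported as (mean, SD, n) be checked without raw data.
    """
    t, p = stats.ttest_ind_from_stats(mean_x, sd_x, n_x, mean_y, sd_y, n_y,
                                      equal_var=True)
    fc, ci = fold_change(mean_x, sd_x, n_x, mean_y, sd_y, n_y)
    return StatResult(
        variable=variable, groups=groups, test_used="unpaired_t",
        statistic=float(t), df=float(n_x + n_y - 2), p_two_tailed=float(p),
        n=(n_x, n_y), fold_change=fc, fc_ci95=ci,
        mean_difference=mean_y - mean_x,
    )


def group_comparison(
    sample_x, sample_y,
    variable: str = "", groups: tuple[str, str] = ("x", "y"),
    force_gate: str | None = None,
) -> StatResult:
    """Gate-routed two-group contrast with fold change.

    Pooled-variance unpaired two-tailed t when both samples pass the
    Gaussian gate, two-tailed Mann–Whitney U otherwise.  ``force_gate``
    overrides the gate ("gaussian" / "non_gaussian") for diagnostics.
    """
    x, y = _clean(sample_x), _clean(sample_y)
    if len(x) < 3 or len(y) < 3:
        raise StatsError("need >= 3 observations per group")
    gate = force_gate or (
        "gaussian"
        if gaussian_gate(x) == "gaussian" and gaussian_gate(y) == "gaussian"
        else "non_gaussian"
    )
    if gate == "gaussian":
        if np.array_equal(np.sort(x), np.sort(y)):
            t, p, test = 0.0, 1.0, "unpaired_t"
        else:
            t, p = stats.ttest_ind(x, y, equal_var=True)
            test = "unpaired_t"
        stat, df = float(t), float(len(x) + len(y) - 2)
    else:
        u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        stat, df, test = float(u), None, "mann_whitney"
    if x.mean() > 0:
        fc, ci = fold_change(x.mean(), x.std(ddof=1), len(x),
                             y.mean(), y.std(ddof=1), len(y))
    else:
        fc, ci = None, None
    return StatResult(
        variable=variable, groups=groups, test_used=test,
        statistic=stat, df=df, p_two_tailed=float(p),
        n=(len(x), len(y)), fold_change=fc, fc_ci95=ci,
        mean_difference=float(y.mean() - x.mean()),
    )


def anova_tukey(groups_by_level: dict, variable: str = "") -> dict:
    """One-way ANOVA across severity levels with Tukey HSD pairwise results.

    Levels with fewer than two observations are dropped with a warning.
    Returns ``{"f", "p", "levels", "pairwise": {(a, b): adjusted_p}}``.
    """
    levels, samples = [], []
    for lvl in sorted(groups_by_level):
        s = _clean(groups_by_level[lvl])
        if len(s) < 2:
            warnings.warn(f"level {lvl!r} has n < 2; dropped from ANOVA")
            continue
        levels.append(lvl)
        samples.append(s)
    if len(levels) < 3:
        raise StatsError("need >= 3 usable levels for the severity ANOVA")
    f, p = stats.f_oneway(*samples)
    hsd = stats.tukey_hsd(*samples)
    pairwise = {}
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            pairwise[(levels[i], levels[j])] = float(hsd.pvalue[i, j])
    return {"variable": variable, "f": float(f), "p": float(p),
            "levels": levels, "pairwise": pairwise}


def holm_bonferroni(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Boolean rejection flags under Holm's step-down procedure."""
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    reject = np.zeros(len(p), dtype=bool)
    if ok.sum():
        reject[ok] = multipletests(p[ok], alpha=alpha, method="holm")[0]
    return reject


def correlation_table(
    count_matrix: pd.DataFrame,
    clinical_matrix: pd.DataFrame,
    family: str = "column",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations of every count column against every clinical column.

    Observations are deleted pairwise per cell, so n varies across cells.
    Holm–Bonferroni flags are set within each family: ``"column"`` treats one
    clinical variable's column (across all vascular categories) as a family;
    ``"global"`` corrects over the whole grid.  Cells with n < 3 or zero
    variance are returned with NaN r/p and flagged insignificant.
    """
    if family not in ("column", "global"):
        raise StatsError(f"unknown Holm family {family!r}")
    rows = []
    for clin in clinical_matrix.columns:
        for cat in count_matrix.columns:
            pair = pd.concat([count_matrix[cat], clinical_matrix[clin]], axis=1).dropna()
            n = len(pair)
            if n < 3 or pair.iloc[:, 0].nunique() < 2 or pair.iloc[:, 1].nunique() < 2:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append({"vascular_category": cat, "clinical_variable": clin,
                         "r": float(r), "p": float(p), "n": n})
    table = pd.DataFrame(rows)
    if family == "global":
        table["holm_significant"] = holm_bonferroni(table["p"], alpha)
    else:
        flags = np.zeros(len(table), dtype=bool)
        for clin in clinical_matrix.columns:
            idx = table.index[table["clinical_variable"] == clin]
            flags[idx] = holm_bonferroni(table.loc[idx, "p"], alpha)
        table["holm_significant"] = flags
    return table


def stratify_cohort(meta: pd.DataFrame, scheme: str) -> dict[str, pd.Index]:
    """Split subjects into comparison groups.

    ``moca`` dichotomizes at the conventional screening cut-off (> 26 vs
    <= 26); ``cdr`` forms the 0.5 / 1 / 2 severity levels; ``diagnosis``
    splits normal (NC) vs impaired cognition (IC).  Missing values are
    excluded; the count of excluded subjects is reported under ``_excluded``.
    """
    if scheme == "moca":
        col = meta["MOCA"]
        groups = {"MOCA>26": meta.index[col > 26], "MOCA<=26": meta.index[col <= 26]}
    elif scheme == "cdr":
        col = meta["CDR"]
        groups = {f"CDR{lvl:g}": meta.index[col == lvl] for lvl in (0.5, 1, 2)}
    elif scheme == "diagnosis":
        col = meta["diagnosis"]
        groups = {"NC": meta.index[col == "NC"], "IC": meta.index[col == "IC"]}
    else:
        raise StatsError(f"unknown stratification scheme {scheme!r}")
    n_missing = int(col.isna().sum())
    groups["_excluded"] = meta.index[col.isna()]
    if n_missing:
        warnings.warn(f"{n_missing} subjects excluded from {scheme} stratification")
    return groups


# ---------------------------------------------------------------------------
# Report formatting (display rounding mirrors the tables)
# ---------------------------------------------------------------------------

def round_sig(x: float, sig: int = 2) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def format_result(res: StatResult) -> dict:
    out = {
        "variable": res.variable,
        "groups": "/".join(res.groups),
        "test": res.test_used,
        "statistic": round(res.statistic, 3),
        "p": round_sig(res.p_two_tailed, 2),
        "n": list(res.n),
    }
    if res.fold_change is not None:
        out["FC"] = round(float(res.fold_change), 1)
        if res.fc_ci95 is not None:
            out["FC_CI95"] = [round(float(c), 2) for c in res.fc_ci95]
    return out
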