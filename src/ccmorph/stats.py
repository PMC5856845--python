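"""Statistical toolkit for CCM method-comparison studies.

Implements the analyses a diagnostic/longitudinal CCM study runs on
per-subject endpoint tables:

* ROC analysis with the Hanley–McNeil closed-form AUC standard error and
  accuracy-maximizing cut points;
* comparison of two correlated AUCs (Hanley–McNeil z-test, with the
  correlation of the AUC estimates looked up from a binormal-model grid),
  plus a bootstrap version used as a resampling cross-check;
* Passing–Bablok method-comparison regression (shifted median of pairwise
  slopes with rank-based confidence intervals);
* ordinary least-squares quadratic fit for the NFL↔NFA relation;
* minimum detectable change, MDC = SEM · 1.96 · √2;
* square-root normalization with Shapiro–Wilk reporting;
* baseline-adjusted ANCOVA for two-arm longitudinal change;
* group summaries, percent-of-control, Pearson correlation matrices and
  Tukey HSD multiple comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ROCResult",
    "roc_analysis",
    "hanley_mcneil_se",
    "compare_auc",
    "paired_auc_test",
    "bootstrap_auc_test",
    "PBFit",
    "passing_bablok",
    "QuadFit",
    "fit_quadratic",
    "mdc",
    "sem_from_sd",
    "normalize_variable",
    "AncovaResult",
    "ancova_change",
    "SummaryStats",
    "summarize_groups",
    "GroupSummary",
]


# --------------------------------------------------------------------------
# ROC / AUC


@dataclass
class ROCResult:
    """ROC curve, Mann–Whitney AUC and the accuracy-optimal cut point."""

    auc: float
    se_auc: float
    curve: np.ndarray          # (k, 2) of (1 - specificity, sensitivity)
    cutpoint: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int
    direction: str = "lower"
    cutpoint_youden: float = float("nan")


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Closed-form SE of a Mann–Whitney AUC (Hanley & McNeil 1982).

    Uses the exponential-distribution moments Q1 = A/(2−A) and
    Q2 = 2A²/(1+A).
    """
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a**2)
           + (n_neg - 1) * (q2 - a**2)) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def _mw_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """Concordance P(case score ranks on the case side), ties counting ½."""
    # rank-based: equals pairwise enumeration but O((m+n) log(m+n))
    allv = np.concatenate([cases, controls])
    ranks = sps.rankdata(allv)
    r_case = ranks[: len(cases)].sum()
    m, n = len(cases), len(controls)
    u = r_case - m * (m + 1) / 2.0
    return u / (m * n)


def roc_analysis(values, labels, direction: str = "lower") -> ROCResult:
    """ROC analysis of one endpoint against case/control labels.

    Parameters
    ----------
    values
        Per-subject endpoint values.
    labels
        Boolean (True = case) or any two-valued array where truthy marks
        cases.
    direction
        ``"lower"`` — lower values indicate disease (the CCM convention:
        neuropathy reduces every endpoint); ``"higher"`` for the opposite.

    The AUC is the Mann–Whitney concordance probability (ties count ½)
    with its Hanley–McNeil standard error; the cut point maximizes
    TP + TN over observed thresholds, ties broken toward higher
    sensitivity.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape:
        raise ValueError("values and labels differ in length")
    cases, controls = v[y], v[~y]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be non-empty")
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")

    sgn = -1.0 if direction == "lower" else 1.0
    auc = _mw_auc(sgn * cases, sgn * controls)

    thresholds = np.unique(v)
    best = None
    curve = [(0.0, 0.0)]
    youden_best = None
    for t in thresholds:
        pred = v <= t if direction == "lower" else v >= t
        tp = int((pred & y).sum())
        tn = int((~pred & ~y).sum())
        sens = tp / len(cases)
        spec = tn / len(controls)
        curve.append((1.0 - spec, sens))
        key = (tp + tn, sens)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
        jkey = (sens + spec - 1.0, sens)
        if youden_best is None or jkey > youden_best[0]:
            youden_best = (jkey, t)
    curve.append((1.0, 1.0))
    curve = np.array(sorted(set(curve)))

    _, cut, sens, spec = best
    return ROCResult(
        auc=auc,
        se_auc=hanley_mcneil_se(auc, len(cases), len(controls)),
        curve=curve,
        cutpoint=float(cut),
        sensitivity=sens,
        specificity=spec,
        n_pos=len(cases),
        n_neg=len(controls),
        direction=direction,
        cutpoint_youden=float(youden_best[1]),
    )


# Correlation of two AUC estimates as a function of the average
# within-class score correlation (rows) and the average AUC (columns).
# Regenerated by Monte Carlo from the correlated-binormal rating model
# (paired scores on the same subjects, common AUC); bilinear interpolation
# between grid points.  The rho = 0 row is exactly zero by independence.
_HM_RHO = np.arange(0.0, 0.95, 0.1)
_HM_A = np.array([0.5, 0.6, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 0.975])
_HM_TABLE = np.array([
    [0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.000],
    [0.091, 0.081, 0.112, 0.097, 0.103, 0.074, 0.092, 0.049, 0.038],
    [0.184, 0.180, 0.186, 0.162, 0.169, 0.174, 0.146, 0.125, 0.109],
    [0.301, 0.263, 0.252, 0.275, 0.280, 0.249, 0.241, 0.183, 0.162],
    [0.367, 0.372, 0.359, 0.379, 0.381, 0.334, 0.301, 0.291, 0.232],
    [0.474, 0.475, 0.445, 0.466, 0.458, 0.437, 0.402, 0.378, 0.330],
    [0.567, 0.564, 0.569, 0.556, 0.555, 0.535, 0.513, 0.487, 0.426],
    [0.691, 0.660, 0.657, 0.659, 0.650, 0.638, 0.623, 0.562, 0.560],
    [0.797, 0.777, 0.772, 0.765, 0.768, 0.748, 0.730, 0.701, 0.675],
    [0.885, 0.888, 0.882, 0.876, 0.873, 0.869, 0.859, 0.840, 0.813],
])


def auc_estimate_correlation(score_corr: float, mean_auc: float) -> float:
    """Correlation between two paired AUC estimates (table lookup).

    ``score_corr`` is the mean of the within-case and within-control
    Pearson correlations of the two scores; ``mean_auc`` the average of
    the two AUCs.  Bilinear interpolation on the frozen binormal grid,
    clipped to the grid's hull.
    """
    r = float(np.clip(abs(score_corr), _HM_RHO[0], _HM_RHO[-1]))
    a = float(np.clip(max(mean_auc, 1.0 - mean_auc), _HM_A[0], _HM_A[-1]))
    i = min(int(np.searchsorted(_HM_RHO, r, side="right")) - 1, len(_HM_RHO) - 2)
    j = min(int(np.searchsorted(_HM_A, a, side="right")) - 1, len(_HM_A) - 2)
    tr = (r - _HM_RHO[i]) / (_HM_RHO[i + 1] - _HM_RHO[i])
    ta = (a - _HM_A[j]) / (_HM_A[j + 1] - _HM_A[j])
    t00, t01 = _HM_TABLE[i, j], _HM_TABLE[i, j + 1]
    t10, t11 = _HM_TABLE[i + 1, j], _HM_TABLE[i + 1, j + 1]
    val = (t00 * (1 - tr) * (1 - ta) + t10 * tr * (1 - ta)
           + t01 * (1 - tr) * ta + t11 * tr * ta)
    return float(np.clip(math.copysign(val, score_corr), -1.0, 1.0))


def compare_auc(r1: ROCResult, r2: ROCResult, paired: bool = False,
                score_correlation: float | None = None) -> tuple[float, float]:
    """z-test for the difference of two AUCs (Hanley & McNeil 1983).

    z = (A1 − A2) / √(SE1² + SE2² − 2·r·SE1·SE2), where r is the
    correlation between the AUC estimates — zero for unpaired designs,
    otherwise interpolated from the binormal grid at the mean
    within-class score correlation and mean AUC.

    Returns ``(z, two-sided p)``.
    """
    if paired and (r1.n_pos != r2.n_pos or r1.n_neg != r2.n_neg):
        raise ValueError("paired comparison needs identical group sizes")
    if paired:
        if score_correlation is None:
            raise ValueError("paired comparison needs score_correlation")
        r = auc_estimate_correlation(score_correlation,
                                     0.5 * (r1.auc + r2.auc))
    else:
        r = 0.0
    var = r1.se_auc**2 + r2.se_auc**2 - 2.0 * r * r1.se_auc * r2.se_auc
    if var <= 0:
        return 0.0, 1.0
    z = (r1.auc - r2.auc) / math.sqrt(var)
    return z, 2.0 * sps.norm.sf(abs(z))


def _within_class_corr(v1, v2, labels) -> float:
    y = np.asarray(labels, dtype=bool)
    v1, v2 = np.asarray(v1, float), np.asarray(v2, float)
    rs = []
    for cls in (y, ~y):
        if cls.sum() >= 3 and np.std(v1[cls]) > 0 and np.std(v2[cls]) > 0:
            rs.append(sps.pearsonr(v1[cls], v2[cls])[0])
    return float(np.mean(rs)) if rs else 0.0


def paired_auc_test(values1, values2, labels, direction: str = "lower",
                    ) -> tuple[float, float, ROCResult, ROCResult]:
    """Compare the AUCs of two endpoints measured on the same subjects."""
    r1 = roc_analysis(values1, labels, direction)
    r2 = roc_analysis(values2, labels, direction)
    rho = _within_class_corr(values1, values2, labels)
    z, p = compare_auc(r1, r2, paired=True, score_correlation=rho)
    return z, p, r1, r2


def bootstrap_auc_test(values1, values2, labels, direction: str = "lower",
                       n_boot: int = 500, seed: int = 0) -> tuple[float, float]:
    """Resampling version of the paired AUC comparison (cross-check).

    Bootstraps subjects within class, estimates the SE of A1 − A2
    directly, and returns the normal-theory ``(z, p)``.
    """
    v1, v2 = np.asarray(values1, float), np.asarray(values2, float)
    y = np.asarray(labels, dtype=bool)
    sgn = -1.0 if direction == "lower" else 1.0
    ip, im = np.where(y)[0], np.where(~y)[0]
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(ip, len(ip))
        bm = rng.choice(im, len(im))
        diffs[b] = (_mw_auc(sgn * v1[bp], sgn * v1[bm])
                    - _mw_auc(sgn * v2[bp], sgn * v2[bm]))
    se = float(diffs.std(ddof=1))
    d0 = (_mw_auc(sgn * v1[ip], sgn * v1[im])
          - _mw_auc(sgn * v2[ip], sgn * v2[im]))
    if se == 0:
        return 0.0, 1.0
    z = d0 / se
    return z, 2.0 * sps.norm.sf(abs(z))


# --------------------------------------------------------------------------
# Passing–Bablok


@dataclass
class PBFit:
    """Passing–Bablok regression estimate with 95% confidence bounds."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int


def passing_bablok(x, y, ci: float = 0.95) -> PBFit:
    """Nonparametric method-comparison regression (Passing & Bablok 1983).

    The slope is the shifted median of all pairwise slopes: slopes of
    exactly −1 are discarded and the median index is offset by K, the
    number of slopes below −1, making the estimate invariant to swapping
    the two methods (up to reciprocal).  Confidence bounds come from the
    binomial rank limits of Kendall's tau.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]):
        raise ValueError("all x identical")

    slopes = []
    for i in range(n - 1):
        dx = x[i + 1:] - x[i]
        dy = y[i + 1:] - y[i]
        ok = dx != 0
        s = dy[ok] / dx[ok]
        slopes.extend(s[s != -1.0])
    S = np.sort(slopes)
    N = len(S)
    if N == 0:
        raise ValueError("no valid pairwise slopes")
    K = int((S < -1.0).sum())

    def shifted_median(offset_lo: int, offset_hi: int | None = None) -> float:
        if offset_hi is None:
            offset_hi = offset_lo
        lo = int(np.clip(offset_lo, 0, N - 1))
        hi = int(np.clip(offset_hi, 0, N - 1))
        return 0.5 * (S[lo] + S[hi])

    if N % 2:
        b = shifted_median((N + 1) // 2 - 1 + K)
    else:
        b = shifted_median(N // 2 - 1 + K, N // 2 + K)

    z = sps.norm.ppf(0.5 + ci / 2.0)
    w = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((N - w) / 2.0))
    m2 = N - m1 + 1
    b_lo = S[int(np.clip(m1 + K - 1, 0, N - 1))]
    b_hi = S[int(np.clip(m2 + K - 1, 0, N - 1))]

    a = float(np.median(y - b * x))
    a_lo = float(np.median(y - b_hi * x))
    a_hi = float(np.median(y - b_lo * x))
    return PBFit(float(b), a, (float(b_lo), float(b_hi)),
                 (min(a_lo, a_hi), max(a_lo, a_hi)), n)


# --------------------------------------------------------------------------
# Quadratic NFL <-> NFA model


@dataclass
class QuadFit:
    """Least-squares quadratic y = a·x² + b·x + c with r² and 95% CIs."""

    a: float
    b: float
    c: float
    r2: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    p_a: float = float("nan")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * x**2 + self.b * x + self.c

    def r2_on(self, x, y) -> float:
        """Coefficient of determination of the fixed curve on new data."""
        y = np.asarray(y, dtype=float)
        resid = y - self.predict(x)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            return 1.0
        return 1.0 - float((resid**2).sum()) / ss_tot


def fit_quadratic(x, y) -> QuadFit:
    """OLS fit of y = a·x² + b·x + c (e.g. NFA against NFL, pixel units).

    Columns are scaled to unit norm before solving (the raw design is
    badly conditioned when x spans thousands of pixels); coefficients,
    covariance and t-based 95% CIs are mapped back exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 points")
    if len(np.unique(x)) <= 2:
        raise ValueError("degenerate design: <= 2 distinct x values")
    X = np.column_stack([np.ones_like(x), x, x**2])
    scale = np.linalg.norm(X, axis=0)
    Xs = X / scale
    beta_s, _, _, _ = np.linalg.lstsq(Xs, y, rcond=None)
    beta = beta_s / scale
    resid = y - X @ beta
    dof = n - 3
    sigma2 = float(resid @ resid) / dof
    cov = np.linalg.inv(Xs.T @ Xs) * sigma2
    se = np.sqrt(np.diag(cov)) / scale
    tq = sps.t.ppf(0.975, dof)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    c, b, a = beta
    t_a = a / se[2] if se[2] > 0 else np.inf
    return QuadFit(float(a), float(b), float(c), r2,
                   ci={"c": (c - tq * se[0], c + tq * se[0]),
                       "b": (b - tq * se[1], b + tq * se[1]),
                       "a": (a - tq * se[2], a + tq * se[2])},
                   p_a=float(2 * sps.t.sf(abs(t_a), dof)))


# --------------------------------------------------------------------------
# MDC, normalization


def mdc(sem: float) -> float:
    """Minimum detectable change: SEM · 1.96 · √2."""
    if sem < 0:
        raise ValueError("sem must be >= 0")
    return sem * 1.96 * math.sqrt(2.0)


def sem_from_sd(sd: float, n: int | None = None, icc: float | None = None) -> float:
    """Standard error of measurement.

    With ``n``: the sampling SEM sd/√n.  With ``icc``: the reliability
    SEM sd·√(1 − ICC).  Exactly one of the two must be given.
    """
    if (n is None) == (icc is None):
        raise ValueError("give exactly one of n or icc")
    if n is not None:
        return sd / math.sqrt(n)
    return sd * math.sqrt(1.0 - icc)


def normalize_variable(values) -> dict:
    """Square-root transform with Shapiro–Wilk normality before/after.

    Returns a dict with ``transformed`` plus (W, p) pre and post; W is
    ``None`` (flagged) for degenerate all-equal input.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("square-root transform requires non-negative values")
    t = np.sqrt(v)

    def _sw(a):
        if len(a) < 3 or np.all(a == a[0]):
            return None, None
        w, p = sps.shapiro(a)
        return float(w), float(p)

    w0, p0 = _sw(v)
    w1, p1 = _sw(t)
    return {"transformed": t, "w_pre": w0, "p_pre": p0,
            "w_post": w1, "p_post": p1}


# --------------------------------------------------------------------------
# ANCOVA


@dataclass
class AncovaResult:
    """Baseline-adjusted treatment effect from a two-arm change analysis."""

    effect: float       # adjusted net change, treatment minus reference arm
    se: float
    p: float
    baseline_coef: float
    arm_means: dict[str, float]   # raw mean change per arm
    arm_sems: dict[str, float]


def ancova_change(baseline, followup, arm, treatment_label=None) -> AncovaResult:
    """ANCOVA of follow-up on treatment arm with baseline as covariate.

    Fits ``followup ~ baseline + arm`` by OLS and reports the arm
    coefficient (the baseline-adjusted net change attributable to
    treatment), its SE and two-sided p.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    arm = np.asarray(arm)
    if not (len(b) == len(f) == len(arm)):
        raise ValueError("inputs differ in length")
    levels = sorted(pd.unique(arm))
    if len(levels) != 2:
        raise ValueError("exactly two arms required")
    if treatment_label is None:
        treatment_label = levels[1]
    ind = (arm == treatment_label).astype(float)
    X = sm.add_constant(np.column_stack([b, ind]))
    res = sm.OLS(f, X).fit()

    delta = f - b
    means, sems = {}, {}
    for lv in levels:
        d = delta[arm == lv]
        means[str(lv)] = float(d.mean())
        sems[str(lv)] = float(d.std(ddof=1) / math.sqrt(len(d))) if len(d) > 1 else float("nan")
    return AncovaResult(
        effect=float(res.params[2]), se=float(res.bse[2]),
        p=float(res.pvalues[2]), baseline_coef=float(res.params[1]),
        arm_means=means, arm_sems=sems,
    )


# --------------------------------------------------------------------------
# Group summaries


@dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float
    sem: float
    median: float
    iqr: float
    min: float
    max: float
    percent_of_control: float = float("nan")


@dataclass
class GroupSummary:
    """Per-group descriptive statistics, correlations and Tukey contrasts."""

    stats: dict[str, dict[str, SummaryStats]]      # group -> variable -> stats
    correlations: dict[str, pd.DataFrame]          # group -> Pearson r matrix
    tukey: dict[str, pd.DataFrame]                 # variable -> contrasts


def _summary(v: np.ndarray, control_mean: float | None) -> SummaryStats:
    n = len(v)
    sd = float(np.std(v, ddof=1)) if n > 1 else float("nan")
    q75, q25 = np.percentile(v, [75, 25])
    pct = float("nan")
    if control_mean not in (None, 0):
        pct = 100.0 * float(v.mean()) / control_mean
    return SummaryStats(
        n=n, mean=float(v.mean()), sd=sd,
        sem=sd / math.sqrt(n) if n > 1 else float("nan"),
        median=float(np.median(v)), iqr=float(q75 - q25),
        min=float(v.min()), max=float(v.max()),
        percent_of_control=pct,
    )


def summarize_groups(table: pd.DataFrame, control_label: str,
                     variables: list[str] | None = None,
                     group_col: str = "group") -> GroupSummary:
    """Descriptive statistics per group and variable.

    ``table`` holds one row per subject with a group column and numeric
    endpoint columns.  Reports n/mean/sd/sem/median/IQR/range,
    percent-of-control means, within-group Pearson correlation matrices,
    and Tukey HSD pairwise group contrasts per variable.
    """
    if control_label not in set(table[group_col]):
        raise ValueError(f"control group {control_label!r} absent")
    if variables is None:
        variables = [c for c in table.columns
                     if c != group_col and pd.api.types.is_numeric_dtype(table[c])]

    ctrl = table[table[group_col] == control_label]
    out: dict[str, dict[str, SummaryStats]] = {}
    corrs: dict[str, pd.DataFrame] = {}
    for grp, sub in table.groupby(group_col):
        out[str(grp)] = {
            var: _summary(sub[var].to_numpy(dtype=float),
                          float(ctrl[var].mean()))
            for var in variables
        }
        corrs[str(grp)] = sub[variables].corr(method="pearson")

    tukey: dict[str, pd.DataFrame] = {}
    if table[group_col].nunique() >= 2:
        for var in variables:
            res = pairwise_tukeyhsd(table[var].to_numpy(dtype=float),
                                    table[group_col].to_numpy())
            tukey[var] = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0])
    return GroupSummary(stats=out, correlations=corrs, tukey=tukey)
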