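"""Validation experiments: phantom recovery and statistical calibration.

Since no raw CCM study images are publicly available, the package's
correctness case rests on controlled experiments against ground truth and
independent oracles:

* end-to-end phantom recovery (segmentation + morphometry vs generator
  truth);
* brute-force enumeration oracles for the ROC AUC and the Passing–Bablok
  slope;
* simulation calibration of the quadratic NFL↔NFA model CIs, the ANCOVA
  treatment-effect estimator, ROC behaviour under the null, and the
  closed-form correlated-AUC z-test against a bootstrap oracle;
* the width-dropout structure of the synthetic neuropathy operator.

Every experiment takes an explicit seed and returns plain dicts of
numbers, so the same code drives both the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import stats as st
from .morphometry import analyze_mask
from .segmentation import SegParams, segment_nerves
from .synthetic import (CohortSpec, GroupSpec, apply_neuropathy,
                        generate_cohort, generate_longitudinal_cohort,
                        generate_plexus, random_plexus)
from .widths import WidthDistribution, average_distributions, midwidth_dropout

__all__ = [
    "phantom_recovery",
    "auc_oracle_max_error",
    "pb_oracle_max_error",
    "quadratic_simulation",
    "mdc_closed_form_max_error",
    "dropout_severity_curves",
    "ancova_calibration",
    "null_diagnostic_aucs",
    "hm_vs_bootstrap_rms",
]


# --------------------------------------------------------------------------
# phantom recovery (integration)


def phantom_recovery(seed: int = 0, n_images: int = 50,
                     seg_params: SegParams | None = None) -> dict:
    """Segment + measure ``n_images`` random phantoms and score vs truth.

    Returns the fraction of images with exactly recovered NFD, the median
    relative NFL error, the mean and median signed width error (µm), and
    the median relative deviation of NFA from the analytic Σ width·length
    area.
    """
    sp = seg_params or SegParams()
    rng = np.random.default_rng(seed)
    nfd_ok = 0
    nfl_err, mw_err, nfa_err = [], [], []
    for _ in range(n_images):
        spec = random_plexus(int(rng.integers(2**31)))
        img, truth = generate_plexus(spec)
        cal = img.calibration
        var, _, _ = analyze_mask(segment_nerves(img, sp))
        nfd_ok += var.nfd == truth.nfd
        nfl_err.append(abs(var.nfl / truth.nfl - 1.0))
        mw_err.append(var.mean_width_um - truth.mean_width_um)
        analytic_px = sum(
            (w / cal.pixel_pitch_um) * (L / cal.pixel_pitch_um)
            for w, L in zip(truth.fiber_widths_um, truth.fiber_lengths_um))
        nfa_true = analytic_px * cal.pixel_area_um2 / cal.field_area_mm2
        nfa_err.append(abs(var.nfa_fiji / nfa_true - 1.0))
    return {
        "n_images": n_images,
        "nfd_exact_fraction": nfd_ok / n_images,
        "nfl_median_rel_error": float(np.median(nfl_err)),
        "mean_width_mean_error_um": float(np.mean(mw_err)),
        "mean_width_median_abs_error_um": float(np.median(np.abs(mw_err))),
        "nfa_median_rel_error": float(np.median(nfa_err)),
    }


# --------------------------------------------------------------------------
# oracles


def _brute_force_auc(values, labels, direction="lower") -> float:
    v = np.asarray(values, float)
    y = np.asarray(labels, bool)
    cases, controls = v[y], v[~y]
    total = 0.0
    for c in cases:
        for k in controls:
            if (c < k) if direction == "lower" else (c > k):
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(cases) * len(controls))


def auc_oracle_max_error(seed: int = 0, n_datasets: int = 200) -> float:
    """Max |roc_analysis AUC − pairwise enumeration| over random datasets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_datasets):
        n = int(rng.integers(4, 51))
        v = rng.integers(0, 15, size=n).astype(float)
        y = rng.random(n) < rng.uniform(0.25, 0.75)
        if y.all() or not y.any():
            continue
        a1 = st.roc_analysis(v, y, "lower").auc
        worst = max(worst, abs(a1 - _brute_force_auc(v, y)))
    return worst


def _brute_force_pb(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    S = []
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            if x[j] != x[i]:
                s = (y[j] - y[i]) / (x[j] - x[i])
                if s != -1.0:
                    S.append(s)
    S = np.sort(S)
    N, K = len(S), int((np.sort(S) < -1).sum())
    if N % 2:
        return float(S[(N + 1) // 2 - 1 + K])
    return float(0.5 * (S[N // 2 - 1 + K] + S[min(N // 2 + K, N - 1)]))


def pb_oracle_max_error(seed: int = 0, n_fixtures: int = 100) -> dict:
    """Slope agreement with brute force + exactness of affine equivariance.

    Fixtures emulate method-comparison data with a positive relation and
    well-separated x, so every pairwise slope is positive — the regime in
    which the shifted-median estimator is exactly equivariant under
    positive affine maps of y (no slope can cross the −1 shift point).
    """
    rng = np.random.default_rng(seed)
    worst_slope = worst_equiv = 0.0
    for _ in range(n_fixtures):
        n = int(rng.integers(5, 26))
        x = np.cumsum(rng.uniform(1.0, 2.0, size=n))
        y = rng.uniform(1.0, 2.0) * x + rng.uniform(-0.3, 0.3, size=n)
        fit = st.passing_bablok(x, y)
        worst_slope = max(worst_slope, abs(fit.slope - _brute_force_pb(x, y)))
        a, b = rng.uniform(0.5, 3.0), rng.uniform(-5, 5)
        fit2 = st.passing_bablok(x, a * y + b)
        worst_equiv = max(worst_equiv,
                          abs(fit2.slope - a * fit.slope),
                          abs(fit2.intercept - (a * fit.intercept + b)))
    return {"max_slope_error": worst_slope, "max_equivariance_error": worst_equiv}


# --------------------------------------------------------------------------
# quadratic model simulation

_QUAD_TRUTH = (2.78e-4, 0.72, 471.0)   # published NFL↔NFA pixel-unit relation


def quadratic_simulation(seed: int = 0, n_reps: int = 100,
                         n_subjects: int = 192, target_r2: float = 0.8) -> dict:
    """CI coverage of the quadratic fit under noise calibrated to r² ≈ 0.8.

    Data are generated from the published curve over the observed NFL
    pixel range; Gaussian noise is scaled so the population r² equals
    ``target_r2``.  Also reports the worst coefficient error of a
    noiseless fit.
    """
    a0, b0, c0 = _QUAD_TRUTH
    rng = np.random.default_rng(seed)

    x = np.linspace(200, 4000, 25)
    y = a0 * x**2 + b0 * x + c0
    fit0 = st.fit_quadratic(x, y)
    noiseless = max(abs(fit0.a - a0), abs(fit0.b - b0), abs(fit0.c - c0))

    cover = {"a": 0, "b": 0, "c": 0}
    r2s = []
    for _ in range(n_reps):
        xs = rng.uniform(200, 4000, size=n_subjects)
        signal = a0 * xs**2 + b0 * xs + c0
        sd = np.std(signal) * np.sqrt((1 - target_r2) / target_r2)
        ys = signal + rng.normal(0, sd, size=n_subjects)
        fit = st.fit_quadratic(xs, ys)
        r2s.append(fit.r2)
        for key, truthv in zip(("a", "b", "c"), (a0, b0, c0)):
            lo, hi = fit.ci[key]
            cover[key] += lo <= truthv <= hi
    return {
        "noiseless_max_coef_error": noiseless,
        "coverage_a": cover["a"] / n_reps,
        "coverage_b": cover["b"] / n_reps,
        "coverage_c": cover["c"] / n_reps,
        "mean_sample_r2": float(np.mean(r2s)),
    }


def mdc_closed_form_max_error(n_values: int = 20) -> float:
    """Worst deviation of mdc(s) from s·1.96·√2 over a grid of SEMs."""
    worst = 0.0
    for s in np.linspace(0.0, 50.0, n_values):
        worst = max(worst, abs(st.mdc(s) - s * 1.96 * np.sqrt(2.0)))
    return worst


# --------------------------------------------------------------------------
# width dropout structure


def dropout_severity_curves(seed: int = 0, n_cohorts: int = 50,
                            severities=(0.0, 0.25, 0.5, 0.75, 1.0)) -> dict:
    """Mid-width band retention and mean width vs neuropathy severity.

    For each severity the generator's own truth (fiber widths weighted by
    length) is histogrammed across ``n_cohorts`` seeded plexus specs; the
    2.8–4.0 µm band mass is referenced to the severity-0 cohort.
    """
    rng = np.random.default_rng(seed)
    base = [random_plexus(int(rng.integers(2**31))) for _ in range(n_cohorts)]
    cal = base[0].calibration
    pitch = cal.pixel_pitch_um

    def truth_hist(specs) -> WidthDistribution:
        counts = np.zeros(8)
        for sp in specs:
            for f in sp.fibers:
                b = int(np.clip(round(f.width_um / pitch), 1, 8))
                counts[b - 1] += 1.0
        return WidthDistribution(np.arange(1, 9) * pitch, counts / counts.sum())

    ref = truth_hist(base)
    ratios, widths = [], []
    for sev in severities:
        degraded = [apply_neuropathy(sp, sev) for sp in base]
        ratios.append(midwidth_dropout(truth_hist(degraded), ref, (2.8, 4.0)))
        widths.append(float(np.mean(
            [f.width_um for sp in degraded for f in sp.fibers])))
    return {"severities": list(severities),
            "band_retention": ratios,
            "mean_width_um": widths}


# --------------------------------------------------------------------------
# ANCOVA calibration


def ancova_calibration(seed: int = 0, n_reps: int = 100, n_null: int = 300,
                       n_per_arm: int = 15, effect: float = 3000.0,
                       variable: str = "nfa_fiji") -> dict:
    """Coverage of the ANCOVA effect estimate and null type-I error.

    ``n_null`` null replicates (no effect) estimate the rejection rate at
    α = 0.05; more are used than effect replicates since a rate estimate
    needs tighter binomial error.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    rejections = 0
    for _ in range(n_reps):
        df = generate_longitudinal_cohort(
            seed=int(rng.integers(2**31)), n_per_arm=n_per_arm,
            effect={variable: effect})
        b = df[df.visit == "baseline"].set_index("subject_id")
        f = df[df.visit == "followup"].loc[:, ["subject_id", variable]]
        f = f.set_index("subject_id").loc[b.index, variable].to_numpy()
        res = st.ancova_change(b[variable].to_numpy(), f,
                               b["arm"].to_numpy())
        covered += abs(res.effect - effect) <= 2.0 * res.se
    for _ in range(n_null):
        df = generate_longitudinal_cohort(
            seed=int(rng.integers(2**31)), n_per_arm=n_per_arm)
        b = df[df.visit == "baseline"].set_index("subject_id")
        f = df[df.visit == "followup"].set_index("subject_id")
        res = st.ancova_change(b[variable].to_numpy(),
                               f.loc[b.index, variable].to_numpy(),
                               b["arm"].to_numpy())
        rejections += res.p < 0.05
    return {"coverage_2se": covered / n_reps,
            "type_i_error": rejections / n_null,
            "effect": effect, "n_per_arm": n_per_arm}


# --------------------------------------------------------------------------
# null diagnostic study


def null_diagnostic_aucs(seed: int = 0, n_per_group: int = 48) -> dict:
    """AUCs of a diagnostic run on two identically distributed groups.

    Both groups are drawn from the control population; each variable's
    AUC should fall inside the 95% Monte-Carlo band around 0.5.
    """
    from .pipeline import run_diagnostic_study

    ctrl = GroupSpec.from_reference("control", n=n_per_group)
    fake = GroupSpec("case", n_per_group, dict(ctrl.means), dict(ctrl.sds))
    table = generate_cohort(CohortSpec((ctrl, fake), seed=seed))
    report = run_diagnostic_study(table)
    out = {}
    for v, r in report["roc"]["case"].items():
        band = 1.96 * st.hanley_mcneil_se(0.5, r["n_pos"], r["n_neg"])
        out[v] = {"auc": r["auc"], "band_95": band,
                  "inside": bool(abs(r["auc"] - 0.5) <= band)}
    return out


# --------------------------------------------------------------------------
# Hanley–McNeil vs bootstrap


def hm_vs_bootstrap_rms(seed: int = 0, n_datasets: int = 200,
                        n_per_class: int = 20, n_boot: int = 500) -> float:
    """RMS difference of paired-AUC-comparison p-values: closed form vs
    bootstrap resampling, over simulated correlated binormal cohorts."""
    rng = np.random.default_rng(seed)
    diffs = []
    for _ in range(n_datasets):
        rho = rng.uniform(0.3, 0.8)
        a_target = rng.uniform(0.65, 0.9)
        delta = sps.norm.ppf(a_target) * np.sqrt(2.0)
        L = np.linalg.cholesky([[1.0, rho], [rho, 1.0]])
        cases = rng.standard_normal((n_per_class, 2)) @ L.T + delta
        ctrls = rng.standard_normal((n_per_class, 2)) @ L.T
        v1 = np.concatenate([cases[:, 0], ctrls[:, 0]])
        v2 = np.concatenate([cases[:, 1], ctrls[:, 1]])
        y = np.concatenate([np.ones(n_per_class, bool),
                            np.zeros(n_per_class, bool)])
        _, p_hm, *_ = st.paired_auc_test(v1, v2, y, "higher")
        _, p_bs = st.bootstrap_auc_test(v1, v2, y, "higher",
                                        n_boot=n_boot,
                                        seed=int(rng.integers(2**31)))
        diffs.append(p_hm - p_bs)
    return float(np.sqrt(np.mean(np.square(diffs))))
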