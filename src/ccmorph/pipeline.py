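"""End-to-end study orchestration.

Two study designs are supported, mirroring how CCM morphometry is used
clinically:

* **diagnostic (cross-sectional)** — several groups including a healthy
  control group; per-variable descriptive statistics and
  percent-of-control, ROC/AUC against control with accuracy-optimal cut
  points, paired comparisons of AUCs between variables, within-group
  correlation matrices, the quadratic NFL↔NFA relation in pixel units,
  and group width distributions with mid-width dropout ratios;
* **longitudinal (two-arm intervention)** — baseline and follow-up
  visits; per-arm mean change ± SEM, baseline-adjusted ANCOVA treatment
  effect, and the minimum detectable change gate.

Reports are plain nested dicts of JSON-serializable values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .io import CCMImage, CCMVariables, Calibration, DEFAULT_CALIBRATION
from .morphometry import analyze_mask
from .segmentation import SegParams, segment_nerves
from .widths import (DEFAULT_DROPOUT_BAND_UM, WidthDistribution,
                     average_distributions, midwidth_dropout, width_histogram)

__all__ = [
    "StudyConfig",
    "analyze_image",
    "run_diagnostic_study",
    "run_longitudinal_study",
    "nfl_to_pixels",
    "nfa_to_pixels",
    "report_to_json",
]


@dataclass(frozen=True)
class StudyConfig:
    """All tunables of a study run; everything lands in the report header."""

    calibration: Calibration = DEFAULT_CALIBRATION
    seg_params: SegParams = field(default_factory=SegParams)
    prune_um: float = 6.0
    main_min_length_um: float = 50.0
    branch_min_length_um: float = 10.0
    aggregation: str = "both_eyes"
    variables: tuple[str, ...] = ("nfd", "nbd", "nfl", "nfa_wxl", "nfa_fiji")
    roc_direction: str = "lower"
    dropout_band_um: tuple[float, float] = DEFAULT_DROPOUT_BAND_UM
    seed: int = 0

    def header(self) -> dict:
        d = dataclasses.asdict(self)
        d["calibration"] = dataclasses.asdict(self.calibration)
        d["seg_params"] = dataclasses.asdict(self.seg_params)
        return d


def analyze_image(image: CCMImage, config: StudyConfig = StudyConfig()
                  ) -> tuple[CCMVariables, WidthDistribution | None]:
    """Segment one frame and compute its endpoint variables.

    Deterministic: the same image and config always give the same record.
    Returns the variables and the width distribution (None for an empty
    mask).
    """
    mask = segment_nerves(image, config.seg_params)
    var, _, wp = analyze_mask(
        mask, prune_um=config.prune_um,
        main_min_length_um=config.main_min_length_um,
        branch_min_length_um=config.branch_min_length_um)
    dist = width_histogram(wp) if len(wp.widths_px) else None
    return var, dist


def nfl_to_pixels(nfl_mm_mm2: np.ndarray | float, cal: Calibration) -> np.ndarray:
    """NFL (mm/mm²) → total skeleton pixel count of one frame."""
    return np.asarray(nfl_mm_mm2) * 1000.0 * cal.field_area_mm2 / cal.pixel_pitch_um


def nfa_to_pixels(nfa_um2_mm2: np.ndarray | float, cal: Calibration) -> np.ndarray:
    """NFA (µm²/mm²) → mask pixel count of one frame."""
    return np.asarray(nfa_um2_mm2) * cal.field_area_mm2 / cal.pixel_area_um2


def run_diagnostic_study(
    table: pd.DataFrame,
    config: StudyConfig = StudyConfig(),
    control_label: str = "control",
    width_distributions: dict[str, list[WidthDistribution]] | None = None,
) -> dict:
    """Cross-sectional analysis of a per-subject endpoint table.

    ``table`` needs a ``group`` column and the endpoint columns named in
    ``config.variables``; ``width_distributions`` optionally maps group
    label → per-subject normalized width histograms.
    """
    groups = list(pd.unique(table["group"]))
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    if len(groups) < 2:
        raise ValueError("need at least two groups including control")
    variables = [v for v in config.variables if v in table.columns]

    summary = st.summarize_groups(table, control_label, variables)
    report: dict = {"config": config.header(), "kind": "diagnostic"}
    report["groups"] = {
        g: {v: dataclasses.asdict(s) for v, s in gv.items()}
        for g, gv in summary.stats.items()
    }
    report["correlations"] = {g: m.to_dict() for g, m in summary.correlations.items()}
    report["tukey"] = {v: df.to_dict(orient="records")
                      for v, df in summary.tukey.items()}

    # normality / square-root transform bookkeeping for the area variables
    report["normality"] = {}
    for v in variables:
        vals = table[v].to_numpy(dtype=float)
        if np.all(vals >= 0):
            nz = st.normalize_variable(vals)
            report["normality"][v] = {k: nz[k] for k in
                                      ("w_pre", "p_pre", "w_post", "p_post")}

    ctrl = table[table["group"] == control_label]
    roc: dict = {}
    auc_comparisons: dict = {}
    for g in groups:
        if g == control_label:
            continue
        sub = table[table["group"] == g]
        merged = pd.concat([sub, ctrl])
        labels = (merged["group"] == g).to_numpy()
        roc[g] = {}
        for v in variables:
            r = st.roc_analysis(merged[v].to_numpy(dtype=float), labels,
                                config.roc_direction)
            roc[g][v] = {
                "auc": r.auc, "se_auc": r.se_auc, "cutpoint": r.cutpoint,
                "sensitivity": r.sensitivity, "specificity": r.specificity,
                "n_pos": r.n_pos, "n_neg": r.n_neg,
            }
        auc_comparisons[g] = {}
        for v1, v2 in combinations(variables, 2):
            z, p, *_ = st.paired_auc_test(
                merged[v1].to_numpy(dtype=float),
                merged[v2].to_numpy(dtype=float),
                labels, config.roc_direction)
            auc_comparisons[g][f"{v1}_vs_{v2}"] = {"z": z, "p": p}
    report["roc"] = roc
    report["auc_comparisons"] = auc_comparisons

    if {"nfl", "nfa_fiji"} <= set(variables):
        cal = config.calibration
        x = nfl_to_pixels(table["nfl"].to_numpy(dtype=float), cal)
        y = nfa_to_pixels(table["nfa_fiji"].to_numpy(dtype=float), cal)
        qf = st.fit_quadratic(x, y)
        report["nfl_nfa_quadratic"] = {
            "a": qf.a, "b": qf.b, "c": qf.c, "r2": qf.r2, "p_a": qf.p_a,
            "units": "pixel counts per frame",
        }

    if width_distributions:
        if control_label not in width_distributions:
            raise ValueError("width distributions need the control group")
        ref = average_distributions(width_distributions[control_label])
        wd: dict = {}
        for g, dists in width_distributions.items():
            mean = average_distributions(dists)
            wd[g] = {
                "bin_centers_um": mean.bin_centers_um.tolist(),
                "frequencies": mean.frequencies.tolist(),
                "midwidth_dropout": midwidth_dropout(
                    mean, ref, config.dropout_band_um),
            }
        report["width_distributions"] = wd
    return report


def run_longitudinal_study(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    arms: pd.Series | dict,
    config: StudyConfig = StudyConfig(),
) -> dict:
    """Two-arm change analysis with an MDC gate.

    ``baseline`` and ``followup`` hold one row per subject
    (``subject_id`` column plus endpoints); ``arms`` maps subject_id →
    arm label.  Per variable: raw mean change ± SEM per arm, the
    baseline-adjusted ANCOVA net effect with p-value, the MDC derived
    from the baseline SEM (sd/√n), and whether the |net change| exceeds
    it.
    """
    b = baseline.set_index("subject_id")
    f = followup.set_index("subject_id")
    unmatched = sorted(set(b.index) ^ set(f.index))
    if unmatched:
        raise ValueError(f"unmatched subjects across visits: {unmatched}")
    f = f.loc[b.index]
    arm = pd.Series(arms).loc[b.index].to_numpy()
    if len(pd.unique(arm)) != 2:
        raise ValueError("exactly two arms required")

    variables = [v for v in config.variables if v in b.columns and v in f.columns]
    report: dict = {"config": config.header(), "kind": "longitudinal",
                    "n": len(b), "variables": {}}
    for v in variables:
        bb = b[v].to_numpy(dtype=float)
        ff = f[v].to_numpy(dtype=float)
        res = st.ancova_change(bb, ff, arm)
        sem_b = st.sem_from_sd(float(np.std(bb, ddof=1)), n=len(bb))
        m = st.mdc(sem_b)
        arms_sorted = sorted(res.arm_means)
        net = res.arm_means[arms_sorted[1]] - res.arm_means[arms_sorted[0]]
        report["variables"][v] = {
            "arm_mean_change": res.arm_means,
            "arm_sem_change": res.arm_sems,
            "net_change": net,
            "ancova_effect": res.effect,
            "ancova_se": res.se,
            "ancova_p": res.p,
            "mdc": m,
            "exceeds_mdc": bool(abs(res.effect) > m),
        }
    return report


def report_to_json(report: dict, path: str | Path | None = None) -> str:
    """Serialize a report losslessly to JSON (and optionally to disk)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    s = json.dumps(report, indent=2, default=default, allow_nan=True)
    if path is not None:
        Path(path).write_text(s)
    return s
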