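"""Ground-truth phantoms and cohort simulators.

No raw CCM study data are publicly deposited, so validation rests on two
synthetic stand-ins with exact known truth:

* **Plexus phantoms** — images of smooth, bright curvilinear fiber
  bundles (Gaussian cross-section, optional beading and branches) on a
  noisy background, mimicking the sub-basal nerve plexus at HRT III
  geometry.  The generating spec fixes true NFD/NBD/NFL/widths before any
  degradation, so segmentation and morphometry can be scored against
  truth.
* **Cohort tables** — per-subject endpoint draws from correlated
  truncated-normal group distributions whose means/SDs default to
  published normative values for healthy controls, NDS-banded diabetic
  neuropathy and sarcoidosis-associated small-fiber neuropathy.

A neuropathy operator degrades a plexus spec the way disease degrades
the plexus: fibers are removed with probability peaked at the normal
mean bundle width (~3.2 µm), and surviving fibers may swell.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy.spatial import cKDTree

from .io import Calibration, CCMImage, DEFAULT_CALIBRATION
from .widths import WidthDistribution
from .morphometry import MAX_WIDTH_PX

__all__ = [
    "BranchSpec",
    "FiberSpec",
    "PlexusSpec",
    "PlexusTruth",
    "random_plexus",
    "straight_fiber_spec",
    "generate_plexus",
    "apply_neuropathy",
    "GroupSpec",
    "CohortSpec",
    "generate_cohort",
    "generate_longitudinal_cohort",
    "REFERENCE_GROUPS",
    "COHORT_VARIABLES",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.355; FWHM of a unit-σ Gaussian


@dataclass(frozen=True)
class BranchSpec:
    """A branch hanging off a main fiber."""

    t: float                 # attachment point, fraction of parent arc length
    length_um: float
    width_um: float
    angle_deg: float         # direction relative to the parent tangent

    def __post_init__(self) -> None:
        if not (0.0 <= self.t <= 1.0):
            raise ValueError("attachment t must be in [0, 1]")
        if self.width_um <= 0 or self.length_um <= 0:
            raise ValueError("branch width and length must be > 0")


@dataclass(frozen=True)
class FiberSpec:
    """A main fiber bundle: smooth curve through control points.

    Control points are (row, col) pixel coordinates; the rendered curve
    interpolates them with a cubic spline.  ``width_um`` is the nominal
    full width (the FWHM of the rendered Gaussian cross-section and the
    diameter of the truth mask).
    """

    control_points: tuple[tuple[float, float], ...]
    width_um: float
    branches: tuple[BranchSpec, ...] = ()
    beading_amplitude: float = 0.0   # fractional intensity modulation
    beading_period_um: float = 25.0

    def __post_init__(self) -> None:
        if self.width_um <= 0:
            raise ValueError("width_um must be > 0")
        if len(self.control_points) < 2:
            raise ValueError("need >= 2 control points")
        if not (0.0 <= self.beading_amplitude < 1.0):
            raise ValueError("beading amplitude must be in [0, 1)")


@dataclass(frozen=True)
class PlexusSpec:
    """Everything needed to render one phantom deterministically."""

    fibers: tuple[FiberSpec, ...]
    calibration: Calibration = DEFAULT_CALIBRATION
    background: float = 40.0
    gradient: float = 0.0        # peak-to-peak linear ramp, intensity units
    noise_sd: float = 20.0
    peak_intensity: float = 100.0   # fiber amplitude above background
    seed: int = 0


@dataclass
class PlexusTruth:
    """Ground truth recorded from the spec before degradation."""

    nfd: float                     # fibers/mm²
    nbd: float                     # branches/mm²
    nfl: float                     # mm/mm²
    fiber_widths_um: list[float]   # per curve (mains then branches)
    fiber_lengths_um: list[float]
    mask: np.ndarray               # true fiber footprint
    mean_width_um: float           # length-weighted

    def width_distribution(self, calibration: Calibration) -> WidthDistribution:
        """Length-weighted true width histogram on the integer-px bins."""
        pitch = calibration.pixel_pitch_um
        counts = np.zeros(MAX_WIDTH_PX)
        for w, L in zip(self.fiber_widths_um, self.fiber_lengths_um):
            b = int(np.clip(round(w / pitch), 1, MAX_WIDTH_PX))
            counts[b - 1] += L
        centers = np.arange(1, MAX_WIDTH_PX + 1) * pitch
        return WidthDistribution(centers, counts / counts.sum())


def _dense_curve(points: np.ndarray, step_px: float = 0.25) -> np.ndarray:
    """Cubic-spline interpolation of control points, ~step_px spacing."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 2:
        n = max(int(np.hypot(*(pts[1] - pts[0])) / step_px), 2)
        t = np.linspace(0, 1, n)
        return pts[0] + t[:, None] * (pts[1] - pts[0])
    k = min(3, len(pts) - 1)
    tck, _ = interpolate.splprep(pts.T, s=0, k=k)
    # estimate arc length, then resample densely
    u = np.linspace(0, 1, 200)
    xy = np.array(interpolate.splev(u, tck)).T
    L = np.sum(np.hypot(*np.diff(xy, axis=0).T))
    u = np.linspace(0, 1, max(int(L / step_px), 2))
    return np.array(interpolate.splev(u, tck)).T


def _arc_lengths(curve: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(curve, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _branch_curve(parent: np.ndarray, b: BranchSpec, pitch: float) -> np.ndarray:
    s = _arc_lengths(parent)
    i = int(np.searchsorted(s, b.t * s[-1]))
    i = min(max(i, 1), len(parent) - 2)
    p0 = parent[i]
    tangent = parent[i + 1] - parent[i - 1]
    tangent = tangent / np.hypot(*tangent)
    th = np.radians(b.angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    d = rot @ tangent
    length_px = b.length_um / pitch
    n = max(int(length_px / 0.25), 2)
    t = np.linspace(0, 1, n)
    return p0 + t[:, None] * d * length_px


def generate_plexus(spec: PlexusSpec) -> tuple[CCMImage, PlexusTruth]:
    """Render a phantom image and its ground truth.

    Fibers are drawn with a Gaussian intensity cross-section whose FWHM
    equals the nominal width (σ = width/2.355), so the half-maximum
    footprint of the rendered fiber coincides with the truth mask.
    Same seed → bit-identical image.
    """
    cal = spec.calibration
    H, W = cal.shape
    pitch = cal.pixel_pitch_um
    rng = np.random.default_rng(spec.seed)

    curves: list[tuple[np.ndarray, float, FiberSpec | None]] = []
    n_branches = 0
    for f in spec.fibers:
        pts = np.asarray(f.control_points, dtype=float)
        if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > H - 1) or \
           np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > W - 1):
            raise ValueError("fiber control points outside the field")
        c = _dense_curve(pts)
        curves.append((c, f.width_um, f))
        for b in f.branches:
            bc = _branch_curve(c, b, pitch)
            bc = bc[(bc[:, 0] >= 0) & (bc[:, 0] <= H - 1)
                    & (bc[:, 1] >= 0) & (bc[:, 1] <= W - 1)]
            if len(bc) >= 2:
                curves.append((bc, b.width_um, None))
                n_branches += 1

    img = np.full((H, W), spec.background, dtype=float)
    if spec.gradient:
        img += spec.gradient * (np.arange(W) / max(W - 1, 1))[None, :]
    signal = np.zeros((H, W))
    mask = np.zeros((H, W), dtype=bool)
    rows, cols = np.mgrid[0:H, 0:W]
    grid = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)

    widths_um, lengths_um = [], []
    for c, w_um, fspec in curves:
        w_px = w_um / pitch
        sigma = w_px / _FWHM
        s = _arc_lengths(c)
        lengths_um.append(float(s[-1]) * pitch)
        widths_um.append(w_um)
        # restrict to the curve's bounding box for speed
        margin = 4 * sigma + 2
        r0, r1 = c[:, 0].min() - margin, c[:, 0].max() + margin
        c0, c1 = c[:, 1].min() - margin, c[:, 1].max() + margin
        sel = ((grid[:, 0] >= r0) & (grid[:, 0] <= r1)
               & (grid[:, 1] >= c0) & (grid[:, 1] <= c1))
        pts = grid[sel]
        d, idx = cKDTree(c).query(pts, workers=-1)
        amp = np.full(len(pts), spec.peak_intensity)
        if fspec is not None and fspec.beading_amplitude > 0:
            phase = 2 * np.pi * (s[idx] * pitch) / fspec.beading_period_um
            amp *= 1.0 + fspec.beading_amplitude * np.sin(phase)
        contrib = amp * np.exp(-0.5 * (d / sigma) ** 2) if sigma > 0 else 0
        flat = np.zeros(H * W)
        flat[np.flatnonzero(sel)] = contrib
        np.maximum(signal, flat.reshape(H, W), out=signal)
        mflat = np.zeros(H * W, dtype=bool)
        mflat[np.flatnonzero(sel)] = d <= w_px / 2.0
        mask |= mflat.reshape(H, W)

    img += signal
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=(H, W))
    image = CCMImage(np.clip(np.rint(img), 0, 255).astype(np.uint8), cal)

    area = cal.field_area_mm2
    total_len = float(sum(lengths_um))
    mean_w = (sum(w * L for w, L in zip(widths_um, lengths_um)) / total_len
              if total_len > 0 else 0.0)
    truth = PlexusTruth(
        nfd=len(spec.fibers) / area,
        nbd=n_branches / area,
        nfl=total_len / 1000.0 / area,
        fiber_widths_um=widths_um,
        fiber_lengths_um=lengths_um,
        mask=mask,
        mean_width_um=mean_w,
    )
    return image, truth


def straight_fiber_spec(width_um: float, row: float | None = None,
                        calibration: Calibration = DEFAULT_CALIBRATION,
                        **kwargs) -> PlexusSpec:
    """One horizontal fiber spanning the full field (handy fixture)."""
    H, W = calibration.shape
    r = H / 2 if row is None else row
    f = FiberSpec(((r, 0.0), (r, W - 1.0)), width_um)
    return PlexusSpec((f,), calibration=calibration, **kwargs)


def random_plexus(
    seed: int,
    n_fibers: int | tuple[int, int] = (2, 8),
    width_px_range: tuple[float, float] = (2.0, 6.0),
    branch_prob: float = 0.4,
    wiggle_px: float = 12.0,
    beading_amplitude: float = 0.15,
    calibration: Calibration = DEFAULT_CALIBRATION,
    **spec_kwargs,
) -> PlexusSpec:
    """Draw a random plexus spec under the standard study conditions.

    Fibers run border-to-border with gentle curvature and near-parallel
    orientations (as sub-basal bundles do), widths uniform in
    ``width_px_range`` pixels, occasional short branches, mild beading.
    Defaults give 2–8 fibers of width 2–6 px with peak/noise ≈ 5.
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_fibers, tuple):
        n_fibers = int(rng.integers(n_fibers[0], n_fibers[1] + 1))
    H, W = calibration.shape
    pitch = calibration.pixel_pitch_um

    # spread fibers across the field to keep them resolvable
    lanes = np.linspace(0.12 * H, 0.88 * H, n_fibers)
    rng.shuffle(lanes)
    base_angle = rng.uniform(-20, 20)
    fibers = []
    for r0 in lanes:
        angle = np.radians(base_angle + rng.uniform(-8, 8))
        xs = np.linspace(0, W - 1, 6)
        rows = r0 + np.tan(angle) * (xs - W / 2)
        rows += rng.normal(0, wiggle_px, size=len(xs)) * np.sin(
            np.linspace(0, np.pi, len(xs)))
        rows = np.clip(rows, 2, H - 3)
        w_px = rng.uniform(*width_px_range)
        branches = []
        if rng.random() < branch_prob:
            branches.append(BranchSpec(
                t=float(rng.uniform(0.25, 0.75)),
                length_um=float(rng.uniform(40, 90)),
                width_um=float(rng.uniform(width_px_range[0],
                                           w_px) * pitch),
                angle_deg=float(rng.choice([-1, 1]) * rng.uniform(35, 65)),
            ))
        fibers.append(FiberSpec(
            control_points=tuple((float(r), float(x)) for r, x in zip(rows, xs)),
            width_um=float(w_px * pitch),
            branches=tuple(branches),
            beading_amplitude=beading_amplitude,
        ))
    return PlexusSpec(tuple(fibers), calibration=calibration,
                      seed=int(rng.integers(2**31)), **spec_kwargs)


#: Center and spread of the width-selective fiber-removal kernel (µm):
#: dropout is strongest around the normal mean bundle width.
DROPOUT_CENTER_UM = 3.2
DROPOUT_SD_UM = 0.4


def apply_neuropathy(spec: PlexusSpec, severity: float,
                     swelling: float = 0.10) -> PlexusSpec:
    """Degrade a plexus spec the way small-fiber neuropathy does.

    Each main fiber is removed with probability
    ``severity · exp(−(w − 3.2)²/(2·0.4²))`` — a Gaussian kernel in width
    peaked at the normal mean (~3.2 µm), so mid-width bundles drop out
    preferentially while very thin and thick bundles survive.  Surviving
    fibers swell by a factor ``1 + swelling·severity``.  Randomness is
    derived from the spec's own seed; severity 0 returns the spec
    unchanged.
    """
    if not (0.0 <= severity <= 1.0):
        raise ValueError("severity must be in [0, 1]")
    if severity == 0.0:
        return spec
    rng = np.random.default_rng([spec.seed, 0x5E7, 1])
    kept = []
    for f in spec.fibers:
        p_remove = severity * np.exp(
            -0.5 * ((f.width_um - DROPOUT_CENTER_UM) / DROPOUT_SD_UM) ** 2)
        if rng.random() < p_remove:
            continue
        new_w = f.width_um * (1.0 + swelling * severity)
        kept.append(dataclasses.replace(f, width_um=new_w))
    return dataclasses.replace(spec, fibers=tuple(kept))


# --------------------------------------------------------------------------
# Cohort tables

COHORT_VARIABLES = ("nfd", "nbd", "nfl", "nfa_wxl", "nfa_fiji")

#: Group-level endpoint means (SDs) from published normative/diagnostic
#: CCM morphometry in healthy controls, NDS-banded diabetic neuropathy
#: and sarcoidosis-associated small-fiber neuropathy.  Units: fibers/mm²,
#: branches/mm², mm/mm², µm²/mm², µm²/mm².
REFERENCE_GROUPS: dict[str, dict] = {
    "control": dict(n=48, means=dict(nfd=28.8, nbd=36.5, nfl=17.1,
                                     nfa_wxl=52331, nfa_fiji=30931),
                    sds=dict(nfd=4.8, nbd=14.4, nfl=3.2,
                             nfa_wxl=9344, nfa_fiji=8735)),
    "nds_0_2": dict(n=21, means=dict(nfd=21.5, nbd=21.6, nfl=12.8,
                                     nfa_wxl=39385, nfa_fiji=20966),
                    sds=dict(nfd=7.3, nbd=11.7, nfl=3.4,
                             nfa_wxl=10626, nfa_fiji=7718)),
    "nds_3_5": dict(n=21, means=dict(nfd=20.5, nbd=28.2, nfl=12.7,
                                     nfa_wxl=39843, nfa_fiji=22122),
                    sds=dict(nfd=9.5, nbd=17.3, nfl=5.0,
                             nfa_wxl=14474, nfa_fiji=10740)),
    "nds_6_8": dict(n=19, means=dict(nfd=15.2, nbd=17.2, nfl=9.6,
                                     nfa_wxl=30340, nfa_fiji=16414),
                    sds=dict(nfd=8.7, nbd=13.2, nfl=4.3,
                             nfa_wxl=12571, nfa_fiji=7594)),
    "nds_9_10": dict(n=20, means=dict(nfd=10.3, nbd=10.8, nfl=7.3,
                                      nfa_wxl=28827, nfa_fiji=12516),
                     sds=dict(nfd=8.5, nbd=10.7, nfl=4.7,
                              nfa_wxl=13603, nfa_fiji=7773)),
    "sarcoidosis": dict(n=63, means=dict(nfd=19.2, nbd=25.5, nfl=12.7,
                                         nfa_wxl=46890, nfa_fiji=19243),
                        sds=dict(nfd=5.4, nbd=11.8, nfl=2.9,
                                 nfa_wxl=10737, nfa_fiji=5407)),
}


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: endpoint means/SDs and inter-variable correlation."""

    label: str
    n: int
    means: dict
    sds: dict
    correlation: float | np.ndarray = 0.85   # scalar = equicorrelation

    @classmethod
    def from_reference(cls, label: str, n: int | None = None,
                       correlation: float | np.ndarray = 0.85) -> "GroupSpec":
        ref = REFERENCE_GROUPS[label]
        return cls(label, n if n is not None else ref["n"],
                   dict(ref["means"]), dict(ref["sds"]), correlation)


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0
    variables: tuple[str, ...] = COHORT_VARIABLES


def _corr_matrix(corr, k: int) -> np.ndarray:
    if np.isscalar(corr):
        R = np.full((k, k), float(corr))
        np.fill_diagonal(R, 1.0)
    else:
        R = np.asarray(corr, dtype=float)
        if R.shape != (k, k):
            raise ValueError("correlation matrix has wrong shape")
    if np.min(np.linalg.eigvalsh(R)) < -1e-10:
        raise ValueError("correlation matrix not positive semi-definite")
    return R


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a per-subject endpoint table.

    Each group's endpoints are drawn from a correlated multivariate
    normal with the group's means/SDs (values truncated at 0) — the
    population model behind published group-summary tables.  Fully
    seed-reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    k = len(spec.variables)
    sid = 0
    for g in spec.groups:
        mu = np.array([g.means[v] for v in spec.variables], dtype=float)
        sd = np.array([g.sds[v] for v in spec.variables], dtype=float)
        R = _corr_matrix(g.correlation, k)
        cov = np.outer(sd, sd) * R
        draws = rng.multivariate_normal(mu, cov, size=g.n,
                                        method="eigh")
        draws = np.clip(draws, 0.0, None)
        for d in draws:
            rows.append({"subject_id": f"S{sid:05d}", "group": g.label,
                         **{v: float(x) for v, x in zip(spec.variables, d)}})
            sid += 1
    return pd.DataFrame(rows)


def generate_longitudinal_cohort(
    seed: int,
    n_per_arm: int = 15,
    variables: tuple[str, ...] = COHORT_VARIABLES,
    baseline_group: str = "sarcoidosis",
    effect: dict | None = None,
    change_sd_frac: float = 0.25,
    baseline_tracking: float = 0.8,
) -> pd.DataFrame:
    """Two-arm baseline/follow-up table with a known additive effect.

    Baseline values are drawn from the named reference group; follow-up =
    baseline-regressed value + arm effect + noise (``change_sd_frac`` of
    the baseline SD).  ``effect`` maps variable → additive treatment-arm
    effect (default all zero).  Returns long-format rows with columns
    ``subject_id, arm, visit`` plus the variables.
    """
    rng = np.random.default_rng(seed)
    gs = GroupSpec.from_reference(baseline_group, n=2 * n_per_arm)
    base = generate_cohort(CohortSpec((gs,), seed=int(rng.integers(2**31)),
                                      variables=variables))
    arms = np.array(["placebo"] * n_per_arm + ["treatment"] * n_per_arm)
    effect = effect or {}
    rows = []
    for i, (_, r) in enumerate(base.iterrows()):
        arm = arms[i]
        rec_b = {"subject_id": r.subject_id, "arm": arm, "visit": "baseline"}
        rec_f = {"subject_id": r.subject_id, "arm": arm, "visit": "followup"}
        for v in variables:
            sd = gs.sds[v]
            mu = gs.means[v]
            b = float(r[v])
            f = (mu + baseline_tracking * (b - mu)
                 + rng.normal(0, change_sd_frac * sd))
            if arm == "treatment":
                f += float(effect.get(v, 0.0))
            rec_b[v] = b
            rec_f[v] = max(f, 0.0)
        rows.extend([rec_b, rec_f])
    return pd.DataFrame(rows)
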