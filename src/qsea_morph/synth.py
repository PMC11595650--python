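"""Synthetic blastocyst cohorts: timings, metric trajectories, grades,
transfer outcomes, and rendered label masks.

The generator draws per-embryo blastulation timings (tSB, tB, tEB,
t-biopsy, in hours post insemination) and per-metric anchor values at the
tB / tEB / t-biopsy milestones from group-level calibrations (means and
SDs for euploid, aneuploid and live-birth subgroups).  Continuous metric
trajectories are built by exponential interpolation between anchors, so
percent change accumulates multiplicatively and values stay positive.
Labeled mask frames are rendered as nested discs: the outer contour
carries the zp-A anchor, the annulus width and inner-contour eccentricity
jointly carry the zp-T anchor, and an angular sector of the inner disc
carries the ICM.

Ground truth is stored on every embryo so that downstream measurement,
sampling and ranking stages can be validated end to end without clinical
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import (
    LABEL_EMBRYO,
    LABEL_ICM,
    LABEL_ZONA,
    MaskFrame,
)

TIMING_NAMES = ("tSB", "tB", "tEB", "t_biopsy")
MILESTONES = ("tB", "tEB", "t_biopsy")
METRICS = ("zp_A", "emb_A", "zp_T", "ICM_A")

GRADE_TIERS = {
    "AA": "excellent",
    "AB": "good",
    "BA": "good",
    "BB": "average",
    "AC": "average",
    "CA": "average",
    "CC": "low",
    "BC": "low",
    "CB": "low",
}
TIER_ORDER = {"excellent": 3, "good": 2, "average": 1, "low": 0}
TIERS_DESC = ("excellent", "good", "average", "low")

#: minimum interval between blastulation and biopsy; blastocysts are never
#: biopsied within 5 h of tB, so the standardized 5-h assay window always fits
MIN_TB_TO_BIOPSY_H = 5.5


def gardner_tier(grade: str) -> str:
    """Collapse a Gardner ICM/TE letter grade (e.g. 'BA') to its quality tier."""
    try:
        return GRADE_TIERS[grade.upper()]
    except KeyError:
        raise ValueError(f"unknown Gardner grade: {grade!r}") from None


# ---------------------------------------------------------------------------
# calibrations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupCalibration:
    """Group-level distributional anchors for the generator.

    ``timings`` maps each of tSB/tB/tEB/t_biopsy to (mean, sd) in hpi;
    ``anchors`` maps each metric to {milestone: (mean, sd)} with areas in
    µm² and zp_T in µm.  ``anchor_correlation`` is the within-embryo
    equicorrelation of anchor draws (one latent quality factor).
    """

    label: str
    timings: dict[str, tuple[float, float]]
    anchors: dict[str, dict[str, tuple[float, float]]]
    anchor_correlation: float = 0.6

    def __post_init__(self) -> None:
        missing_t = set(TIMING_NAMES) - set(self.timings)
        if missing_t:
            raise ValueError(f"calibration {self.label}: missing timings {sorted(missing_t)}")
        means = [self.timings[t][0] for t in TIMING_NAMES]
        if not all(a <= b for a, b in zip(means, means[1:])):
            raise ValueError(f"calibration {self.label}: mean timings not ordered")
        for name, (_, sd) in self.timings.items():
            if sd < 0:
                raise ValueError(f"calibration {self.label}: negative SD for {name}")
        for metric, per_ms in self.anchors.items():
            missing_m = set(MILESTONES) - set(per_ms)
            if missing_m:
                raise ValueError(
                    f"calibration {self.label}: metric {metric} missing milestones {sorted(missing_m)}"
                )
            for ms, (mean, sd) in per_ms.items():
                if mean <= 0 or sd < 0:
                    raise ValueError(
                        f"calibration {self.label}: bad anchor for {metric}@{ms}: {(mean, sd)}"
                    )
        for ms in MILESTONES:
            zp = self.anchors["zp_A"][ms][0]
            emb = self.anchors["emb_A"][ms][0]
            icm = self.anchors["ICM_A"][ms][0]
            if not (zp >= emb >= icm):
                raise ValueError(
                    f"calibration {self.label}: area anchors not nested at {ms}"
                )
        if not 0.0 <= self.anchor_correlation <= 1.0:
            raise ValueError("anchor_correlation must be in [0, 1]")


def _cal(label, timings, zp_a, emb_a, zp_t, icm_a) -> GroupCalibration:
    return GroupCalibration(
        label=label,
        timings=dict(zip(TIMING_NAMES, timings)),
        anchors={
            "zp_A": dict(zip(MILESTONES, zp_a)),
            "emb_A": dict(zip(MILESTONES, emb_a)),
            "zp_T": dict(zip(MILESTONES, zp_t)),
            "ICM_A": dict(zip(MILESTONES, icm_a)),
        },
    )


#: group-wise means ± SDs of the study population (timings in hpi; areas µm²;
#: zp-T µm), at the tB / tEB / t-biopsy milestones
TABLE1_CALIBRATIONS: dict[str, GroupCalibration] = {
    "aneuploid": _cal(
        "aneuploid",
        [(102.5, 10.5), (113.0, 12.7), (120.9, 14.5), (136.0, 15.2)],
        [(14288, 1257), (17435, 1828), (24082, 5763)],
        [(13349, 1196), (16900, 1867), (23612, 5960)],
        [(16.4, 2.9), (12.9, 2.4), (8.1, 3.2)],
        [(3458, 905), (3497, 1047), (3804, 1471)],
    ),
    "euploid": _cal(
        "euploid",
        [(100.5, 9.6), (109.7, 11.1), (115.9, 12.0), (131.6, 13.7)],
        [(14168, 1119), (17417, 1955), (25438, 5968)],
        [(13249, 1121), (16922, 1986), (25058, 6212)],
        [(16.2, 2.9), (12.6, 2.5), (7.1, 2.7)],
        [(3414, 902), (3460, 1066), (3727, 1469)],
    ),
    "euploid_noLB": _cal(
        "euploid_noLB",
        [(100.3, 9.7), (109.9, 11.2), (116.7, 12.4), (132.4, 13.9)],
        [(14124, 1071), (17482, 2234), (25141, 5873)],
        [(13235, 1107), (16996, 2274), (24694, 6169)],
        [(16.5, 3.0), (12.9, 2.5), (7.3, 2.9)],
        [(3425, 953), (3414, 1078), (3800, 1547)],
    ),
    "euploid_LB": _cal(
        "euploid_LB",
        [(99.0, 9.8), (107.5, 10.9), (112.6, 11.2), (127.1, 12.5)],
        [(14263, 1231), (17542, 1835), (25790, 6159)],
        [(13309, 1121), (17030, 1757), (25512, 6299)],
        [(16.3, 3.1), (12.8, 2.5), (6.9, 2.5)],
        [(3434, 852), (3468, 984), (3541, 1212)],
    ),
}

#: observed euploidy prevalence (886/2184) and live-birth rate among
#: transferred euploid blastocysts (233/548)
P_EUPLOID = 886 / 2184
P_LIVE_BIRTH = 233 / 548


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic cohort draw.

    ``embryos_per_cycle`` maps cohort size to probability; the default is
    1 + Poisson(1.78), truncated at 8, matching the study's mean of ~2.8
    biopsied blastocysts per cycle.
    """

    n_cycles: int
    seed: int
    embryos_per_cycle: dict[int, float] | None = None
    p_euploid: float = P_EUPLOID
    p_live_birth: float = P_LIVE_BIRTH
    grade_association: float = 0.5
    transfer_probability: float = 216 / 237
    frame_grid_min: float = 10.0
    um_per_px: float = 1.0
    image_side: int = 320
    timing_correlation: float = 0.85

    def __post_init__(self) -> None:
        if self.n_cycles <= 0:
            raise ValueError("empty cohort: n_cycles must be >= 1")
        for name in ("p_euploid", "p_live_birth", "grade_association", "transfer_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frame_grid_min <= 0:
            raise ValueError("frame_grid_min must be > 0")
        if self.um_per_px <= 0 or self.image_side <= 0:
            raise ValueError("invalid frame geometry")
        if self.embryos_per_cycle is not None:
            probs = np.array(list(self.embryos_per_cycle.values()), dtype=float)
            if (probs < 0).any() or not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
                raise ValueError("embryos_per_cycle probabilities must sum to 1")
            if any(k < 1 for k in self.embryos_per_cycle):
                raise ValueError("cycles must contain >= 1 embryo")

    def size_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        if self.embryos_per_cycle is not None:
            ks = np.array(sorted(self.embryos_per_cycle), dtype=int)
            ps = np.array([self.embryos_per_cycle[int(k)] for k in ks], dtype=float)
            return ks, ps
        lam = 1.78
        ks = np.arange(1, 9)
        from scipy.stats import poisson

        ps = poisson.pmf(ks - 1, lam)
        ps[-1] += 1.0 - ps.sum()
        return ks, ps / ps.sum()


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricTimeSeries:
    """One metric sampled on a strictly increasing time grid (hpi)."""

    metric: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if (v < 0).any():
            raise ValueError("metric values must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def value_at(self, t: float) -> float:
        """Linear interpolation; endpoints are held outside the span."""
        return float(np.interp(t, self.times, self.values))


def sample_trajectory(
    anchors: dict[str, float],
    timings: dict[str, float],
    grid_spacing_min: float = 10.0,
    metric: str = "metric",
) -> MetricTimeSeries:
    """Build a trajectory through the milestone anchors.

    The series runs on a uniform grid from tB to t-biopsy (milestone times
    inserted exactly), interpolating exponentially — linearly in
    log-value space — between the tB, tEB and t-biopsy anchors.  Each
    segment is therefore monotone, and the series passes through the
    anchors exactly.
    """
    if grid_spacing_min <= 0:
        raise ValueError("grid spacing must be > 0")
    ms_t = np.array([timings[m] for m in MILESTONES], dtype=float)
    if not np.all(np.diff(ms_t) >= 0):
        raise ValueError("milestone timings must be ordered tB <= tEB <= t_biopsy")
    ms_v = np.array([anchors[m] for m in MILESTONES], dtype=float)
    if (ms_v <= 0).any():
        raise ValueError("anchors must be > 0 for exponential interpolation")

    t0, t1 = ms_t[0], ms_t[-1]
    grid = np.arange(t0, t1 + 1e-12, grid_spacing_min / 60.0)
    times = np.union1d(np.round(grid, 9), np.round(ms_t, 9))
    times = times[(times >= t0 - 1e-9) & (times <= t1 + 1e-9)]
    # collapse duplicated milestone/grid points within numerical tolerance
    keep = np.concatenate([[True], np.diff(times) > 1e-9])
    times = times[keep]

    # piecewise-linear in log space; degenerate (zero-length) segments are
    # handled by np.interp's step behavior on equal knots
    uniq_t, idx = np.unique(ms_t, return_index=True)
    log_v = np.log(ms_v)[idx]
    values = np.exp(np.interp(times, uniq_t, log_v))
    # pin the anchors exactly (no round-off through log/exp)
    for tm, vm in zip(ms_t, ms_v):
        j = np.argmin(np.abs(times - tm))
        if abs(times[j] - tm) < 1e-9:
            values[j] = vm
    return MetricTimeSeries(metric=metric, times=times, values=values)


# ---------------------------------------------------------------------------
# grades
# ---------------------------------------------------------------------------

#: marginal tier frequencies used for the uninformative component of grading
_BASE_TIER_PROBS = np.array([0.20, 0.30, 0.30, 0.20])  # excellent..low
_COMPETENCE_TIER = {2: "excellent", 1: "good", 0: "average"}


def assign_grade(competence: int, strength: float, rng: np.random.Generator) -> str:
    """Draw a Gardner quality tier given latent competence.

    ``competence`` is 2 for a euploid embryo with live-birth potential,
    1 for a euploid without it, 0 for an aneuploid.  With probability
    ``strength`` the tier is the deterministic competence-ranked tier;
    otherwise it is drawn from the population marginal independently of
    competence.  At strength 0 grades carry no signal; at strength 1
    competent embryos strictly dominate the tier order.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("association strength must be in [0, 1]")
    if competence not in _COMPETENCE_TIER:
        raise ValueError("competence must be 0, 1 or 2")
    if rng.random() < strength:
        return _COMPETENCE_TIER[competence]
    return str(rng.choice(TIERS_DESC, p=_BASE_TIER_PROBS))


# ---------------------------------------------------------------------------
# frame geometry and rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSpec:
    """Nested-disc geometry of one rendered frame (µm units).

    The zona is the annulus between an outer circle of radius ``r_out``
    and an inner circle of radius ``r_in`` whose center is displaced by
    ``offset``; the ICM is an angular sector of the inner disc covering
    ``icm_fraction`` of its area.
    """

    r_out: float
    r_in: float
    offset: float = 0.0
    icm_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (self.r_out > self.r_in >= 0.0):
            raise ValueError("require r_out > r_in >= 0")
        if self.offset < 0 or self.offset + self.r_in > self.r_out + 1e-9:
            raise ValueError("inner contour must nest inside the outer contour")
        if not 0.0 <= self.icm_fraction < 1.0:
            raise ValueError("icm_fraction must be in [0, 1)")

    @property
    def analytic_zp_thickness(self) -> float:
        """Largest inner-edge-to-outer-edge distance: r_out − r_in + offset."""
        return self.r_out - self.r_in + self.offset


def frame_spec_for(
    zp_A: float,
    zp_T: float,
    emb_A: float | None = None,
    icm_A: float = 0.0,
    min_gap: float = 2.0,
) -> FrameSpec:
    """Geometry realizing a zp-A area and a zp-T thickness.

    The outer radius carries zp_A exactly.  When the annulus width implied
    by the areas cannot reach zp_T (zona thickness routinely exceeds the
    mean annulus width), the inner contour is shrunk and displaced so that
    the maximal edge distance r_out − r_in + offset equals zp_T while a
    ``min_gap`` µm zona rim is kept everywhere (no tangency); the rendered
    emb-A is then smaller than its anchor, which is geometrically
    unavoidable.
    """
    if zp_A <= 0 or zp_T < 0:
        raise ValueError("zp_A must be > 0 and zp_T >= 0")
    r_out = math.sqrt(zp_A / math.pi)
    if zp_T >= 2 * r_out - min_gap:
        raise ValueError("zp_T too large for the zp_A disc")
    w_area = r_out - math.sqrt(emb_A / math.pi) if emb_A is not None and emb_A > 0 else None
    if w_area is not None and w_area <= zp_T <= 2 * w_area - min_gap:
        r_in = r_out - w_area
        offset = zp_T - w_area
    elif w_area is not None and min_gap <= zp_T < w_area:
        r_in = r_out - zp_T
        offset = 0.0
    elif zp_T >= min_gap:
        # annulus width (zp_T+min_gap)/2 plus eccentricity (zp_T-min_gap)/2
        # realizes zp_T exactly while keeping a min_gap rim on the thin side
        w = (zp_T + min_gap) / 2.0
        offset = (zp_T - min_gap) / 2.0
        r_in = r_out - w
    else:
        # zp_T thinner than the rendering margin: a thinner ring would break
        # up under rasterization, so render a concentric min_gap rim (the
        # realized thickness is then min_gap, not zp_T)
        r_in = r_out - min_gap
        offset = 0.0
    if r_in <= 0:
        raise ValueError("geometry collapsed: inner radius <= 0")
    frac = 0.0
    inner_area = math.pi * r_in**2
    if icm_A > 0:
        frac = min(icm_A / inner_area, 0.95)
    return FrameSpec(r_out=r_out, r_in=r_in, offset=offset, icm_fraction=frac)


def render_mask(
    spec: FrameSpec,
    scale: float = 1.0,
    side: int = 320,
    time_hpi: float | None = None,
    center: tuple[float, float] | None = None,
) -> MaskFrame:
    """Rasterize a FrameSpec to a labeled MaskFrame.

    Pixels are labeled by their center coordinates: inside the inner
    circle → embryo proper (or ICM within the sector), inside the outer
    circle only → zona, else background.  The inner center is displaced
    along +x (columns) by ``offset``.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    r_out_px = spec.r_out / scale
    if center is None:
        c = ((side - 1) / 2.0, (side - 1) / 2.0)
    else:
        c = center
    if c[0] - r_out_px < -0.5 or c[1] - r_out_px < -0.5 or c[0] + r_out_px > side - 0.5 or c[1] + r_out_px > side - 0.5:
        raise ValueError("outer contour exceeds the frame")

    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    d_out2 = (yy - c[0]) ** 2 + (xx - c[1]) ** 2
    cx_in = c[1] + spec.offset / scale
    d_in2 = (yy - c[0]) ** 2 + (xx - cx_in) ** 2

    labels = np.zeros((side, side), dtype=np.uint8)
    labels[d_out2 <= r_out_px**2] = LABEL_ZONA
    inner = d_in2 <= (spec.r_in / scale) ** 2
    labels[inner] = LABEL_EMBRYO
    if spec.icm_fraction > 0:
        theta = np.arctan2(yy - c[0], xx - cx_in)
        half_angle = math.pi * spec.icm_fraction
        # sector opposite the displacement direction, away from the thin rim
        ang = np.abs(np.mod(theta - math.pi + math.pi, 2 * math.pi) - math.pi)
        labels[inner & (ang <= half_angle)] = LABEL_ICM
    return MaskFrame(labels=labels, scale=scale, time_hpi=time_hpi)


# ---------------------------------------------------------------------------
# embryos and cohorts
# ---------------------------------------------------------------------------


@dataclass
class EmbryoRecord:
    """One synthetic blastocyst with its ground truth."""

    embryo_id: str
    cycle_id: str
    ploidy: str  # "euploid" | "aneuploid"
    grade_tier: str
    timings: dict[str, float]
    competent: bool
    transferred: bool = False
    transfer_order: int | None = None
    live_birth: bool | None = None
    anchors: dict[str, dict[str, float]] = field(default_factory=dict)
    trajectories: dict[str, MetricTimeSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = [self.timings[k] for k in TIMING_NAMES]
        if not all(a <= b for a, b in zip(t, t[1:])):
            raise ValueError("timings must satisfy tSB <= tB <= tEB <= t_biopsy")
        if self.live_birth is not None and not self.transferred:
            raise ValueError("live_birth recorded for an untransferred embryo")
        if self.transferred and self.ploidy != "euploid":
            raise ValueError("only euploid embryos may be transferred")


@dataclass
class CohortSet:
    """A set of cycles, each holding the blastocysts biopsied in it."""

    embryos: list[EmbryoRecord]
    config: CohortConfig

    @property
    def cycles(self) -> dict[str, list[EmbryoRecord]]:
        out: dict[str, list[EmbryoRecord]] = {}
        for e in self.embryos:
            out.setdefault(e.cycle_id, []).append(e)
        return out

    def mixed_ploidy_cycles(self) -> list[str]:
        """Cycles with >1 embryo containing both euploid and aneuploid."""
        out = []
        for cid, embs in self.cycles.items():
            ploidies = {e.ploidy for e in embs}
            if len(embs) >= 2 and ploidies == {"euploid", "aneuploid"}:
                out.append(cid)
        return out

    def multi_euploid_transferred_cycles(self) -> list[str]:
        """Cycles with >= 2 euploid embryos of which >= 1 was transferred."""
        out = []
        for cid, embs in self.cycles.items():
            eus = [e for e in embs if e.ploidy == "euploid"]
            if len(eus) >= 2 and any(e.transferred for e in eus):
                out.append(cid)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.embryos:
            rows.append(
                {
                    "embryo_id": e.embryo_id,
                    "cycle_id": e.cycle_id,
                    "ploidy": e.ploidy,
                    "grade_tier": e.grade_tier,
                    "tSB": e.timings["tSB"],
                    "tB": e.timings["tB"],
                    "tEB": e.timings["tEB"],
                    "t_biopsy": e.timings["t_biopsy"],
                    "transferred": e.transferred,
                    "transfer_order": e.transfer_order if e.transfer_order is not None else pd.NA,
                    "live_birth": e.live_birth if e.live_birth is not None else pd.NA,
                }
            )
        return pd.DataFrame(rows)

    def trajectories_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.embryos:
            for metric, ts in e.trajectories.items():
                for t, v in zip(ts.times, ts.values):
                    rows.append((e.embryo_id, metric, t, v))
        return pd.DataFrame(rows, columns=["embryo_id", "metric", "time_hpi", "value"])


class CalibrationError(KeyError):
    """A drawn group has no calibration."""


def _equicorr_normals(rng: np.random.Generator, means, sds, rho: float) -> np.ndarray:
    """Correlated normal draws sharing one latent factor (equicorrelation rho)."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    shared = rng.standard_normal()
    eps = rng.standard_normal(len(means))
    z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * eps
    return means + sds * z


def draw_timings(
    cal: GroupCalibration, rng: np.random.Generator, correlation: float, max_attempts: int = 100
) -> dict[str, float]:
    """Correlated-Gaussian timings, rejection-resampled until ordered and
    leaving at least the 5-h assay window between tB and biopsy."""
    means = [cal.timings[k][0] for k in TIMING_NAMES]
    sds = [cal.timings[k][1] for k in TIMING_NAMES]
    for _ in range(max_attempts):
        t = _equicorr_normals(rng, means, sds, correlation)
        if np.all(np.diff(t) >= 0) and (t[3] - t[1]) >= MIN_TB_TO_BIOPSY_H and t[0] > 0:
            return dict(zip(TIMING_NAMES, (float(x) for x in t)))
    raise RuntimeError(
        f"could not draw ordered timings for group {cal.label} in {max_attempts} attempts"
    )


#: log-scale spread of the per-embryo zona annulus area (zp_A − emb_A) factor
_GAP_SIGMA = 0.25


def draw_anchors(cal: GroupCalibration, rng: np.random.Generator) -> dict[str, dict[str, float]]:
    """Per-metric milestone anchors for one embryo.

    zp_A, zp_T and ICM_A are drawn as correlated normals sharing one
    latent quality factor (equicorrelation ``anchor_correlation``),
    floored at a small positive value.  emb_A is derived as zp_A minus a
    positive annulus-area gap drawn lognormally around the calibrated
    mean gap — the two areas are near-duplicates per embryo, and deriving
    one from the other guarantees nesting without biasing either mean.
    ICM_A is capped at 90% of emb_A.

    Milestone ordering (areas up, zp-T down) is not enforced per embryo:
    truncating the joint draw would bias the recovered group means, and
    the calibrated ratio spreads imply a real minority of non-monotone
    embryos (collapses, re-thickening).
    """
    out: dict[str, dict[str, float]] = {}
    for metric in ("zp_A", "zp_T", "ICM_A"):
        means = [cal.anchors[metric][m][0] for m in MILESTONES]
        sds = [cal.anchors[metric][m][1] for m in MILESTONES]
        vals = _equicorr_normals(rng, means, sds, cal.anchor_correlation)
        floor = max(1e-6, 0.01 * min(means))
        out[metric] = {m: float(max(v, floor)) for m, v in zip(MILESTONES, vals)}
    # annulus gap: one per-embryo lognormal factor, unit mean, shared across
    # milestones; scaled by the calibrated mean gap at each milestone
    gap_factor = math.exp(rng.normal(-0.5 * _GAP_SIGMA**2, _GAP_SIGMA))
    out["emb_A"] = {}
    for m in MILESTONES:
        mean_gap = cal.anchors["zp_A"][m][0] - cal.anchors["emb_A"][m][0]
        gap = max(mean_gap * gap_factor, 1e-3)
        out["emb_A"][m] = max(out["zp_A"][m] - gap, 1e-3)
        out["ICM_A"][m] = min(out["ICM_A"][m], 0.9 * out["emb_A"][m])
    return out


def make_embryo(
    embryo_id: str,
    cycle_id: str,
    cal: GroupCalibration,
    ploidy: str,
    competent: bool,
    rng: np.random.Generator,
    grade_association: float = 0.5,
    grid_spacing_min: float = 10.0,
    timing_correlation: float = 0.85,
) -> EmbryoRecord:
    timings = draw_timings(cal, rng, timing_correlation)
    anchors = draw_anchors(cal, rng)
    competence = (2 if competent else 1) if ploidy == "euploid" else 0
    tier = assign_grade(competence, grade_association, rng)
    trajectories = {
        metric: sample_trajectory(anchors[metric], timings, grid_spacing_min, metric=metric)
        for metric in METRICS
    }
    return EmbryoRecord(
        embryo_id=embryo_id,
        cycle_id=cycle_id,
        ploidy=ploidy,
        grade_tier=tier,
        timings=timings,
        competent=competent,
        anchors=anchors,
        trajectories=trajectories,
    )


def sample_group(
    cal: GroupCalibration,
    n: int,
    seed: int,
    grid_spacing_min: float = 10.0,
    ploidy: str = "euploid",
) -> list[EmbryoRecord]:
    """Draw ``n`` embryos from one calibration (one pseudo-cycle each)."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        make_embryo(
            f"{cal.label}-{i:05d}",
            f"cyc-{cal.label}-{i:05d}",
            cal,
            ploidy=ploidy,
            competent=False,
            rng=rng,
            grade_association=0.0,
            grid_spacing_min=grid_spacing_min,
        )
        for i in range(n)
    ]


def sample_cohorts(
    config: CohortConfig,
    calibrations: dict[str, GroupCalibration] | None = None,
) -> CohortSet:
    """Draw a full synthetic cohort set.

    Each cycle draws its size, then each embryo draws ploidy
    (Bernoulli p_euploid), latent live-birth competence for euploids,
    a grade tier, timings and metric trajectories from its group's
    calibration (aneuploid / euploid_LB / euploid_noLB, falling back to
    the pooled euploid calibration if the split is absent).  Transfers
    happen in embryologist priority order (grade tier, random tie-break)
    among euploids, stopping at the first live birth.
    """
    cals = calibrations if calibrations is not None else TABLE1_CALIBRATIONS
    rng = np.random.default_rng(config.seed)
    ks, ps = config.size_distribution()

    def group_cal(ploidy: str, competent: bool) -> GroupCalibration:
        if ploidy == "aneuploid":
            key, fallback = "aneuploid", None
        else:
            key = "euploid_LB" if competent else "euploid_noLB"
            fallback = "euploid"
        if key in cals:
            return cals[key]
        if fallback is not None and fallback in cals:
            return cals[fallback]
        raise CalibrationError(f"missing calibration for group {key!r}")

    embryos: list[EmbryoRecord] = []
    for ci in range(config.n_cycles):
        cid = f"cyc-{ci:05d}"
        n_emb = int(rng.choice(ks, p=ps))
        cycle_embryos: list[EmbryoRecord] = []
        for ei in range(n_emb):
            ploidy = "euploid" if rng.random() < config.p_euploid else "aneuploid"
            competent = bool(ploidy == "euploid" and rng.random() < config.p_live_birth)
            emb = make_embryo(
                f"emb-{ci:05d}-{ei:02d}",
                cid,
                group_cal(ploidy, competent),
                ploidy=ploidy,
                competent=competent,
                rng=rng,
                grade_association=config.grade_association,
                grid_spacing_min=config.frame_grid_min,
                timing_correlation=config.timing_correlation,
            )
            cycle_embryos.append(emb)
        # transfers: euploids in embryologist priority order until first LB
        eus = [e for e in cycle_embryos if e.ploidy == "euploid"]
        if eus and rng.random() < config.transfer_probability:
            priority = sorted(
                eus, key=lambda e: (-TIER_ORDER[e.grade_tier], rng.random())
            )
            order = 1
            for e in priority:
                e.transferred = True
                e.transfer_order = order
                e.live_birth = e.competent
                order += 1
                if e.live_birth:
                    break
        embryos.extend(cycle_embryos)
    return CohortSet(embryos=embryos, config=config)


def render_embryo_frame(
    embryo: EmbryoRecord,
    milestone: str = "t_biopsy",
    scale: float = 1.0,
    side: int = 320,
    min_gap: float | None = None,
) -> MaskFrame:
    """Render the labeled mask of one embryo at a milestone, realizing its
    drawn zp-A and zp-T anchors (see frame_spec_for)."""
    a = embryo.anchors
    gap = 2.0 * scale if min_gap is None else min_gap
    spec = frame_spec_for(
        zp_A=a["zp_A"][milestone],
        zp_T=a["zp_T"][milestone],
        emb_A=a["emb_A"][milestone],
        icm_A=a["ICM_A"][milestone],
        min_gap=gap,
    )
    return render_mask(spec, scale=scale, side=side, time_hpi=embryo.timings[milestone])


# ---------------------------------------------------------------------------
# scenario generator: configured zp-T divergence onset
# ---------------------------------------------------------------------------


def divergent_zpt_groups(
    n_per_group: int,
    seed: int,
    onset_min: int = 150,
    step_um: float = 1.0,
    slope_after: float = 0.01,
    between_sd: float = 2.0,
    within_sd: float = 0.8,
    offsets_min: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two groups of zp-T assay profiles whose means separate from a
    configured onset offset.

    Both groups thin linearly from 16.3 µm with shared per-embryo random
    intercepts (SD ``between_sd``) and residual noise (SD ``within_sd``);
    from ``onset_min`` on, group B lags by ``step_um`` plus
    ``slope_after`` µm per minute.  Returns (A, B) arrays of shape
    (n, n_offsets) on the standard 0..300-min half-hour grid.
    """
    if offsets_min is None:
        offsets_min = np.arange(0, 301, 30)
    rng = np.random.default_rng(seed)
    t = np.asarray(offsets_min, dtype=float)
    base = 16.3 - 0.012 * t

    def group(shift: np.ndarray) -> np.ndarray:
        b = rng.normal(0.0, between_sd, size=(n_per_group, 1))
        e = rng.normal(0.0, within_sd, size=(n_per_group, len(t)))
        return np.maximum(base + shift + b + e, 0.05)

    lag = np.where(t >= onset_min, step_um + slope_after * (t - onset_min), 0.0)
    return group(np.zeros_like(t)), group(lag)
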