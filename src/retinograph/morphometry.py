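"""Centerline-based vascular biomarkers.

Three families of per-image biomarkers are computed from traced centerlines:

* fourteen curvature/tortuosity metrics per vessel segment,
* eight geometric optimality metrics per bifurcation junction,
* three fractal dimensions (box, information, correlation) of the
  centerline point set.

Curvature is obtained from an arc-length-resampled smoothing spline, so all
metrics are well defined for hand-traced polylines with click jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate
from scipy.integrate import cumulative_trapezoid
from scipy.spatial import cKDTree

__all__ = [
    "CenterlineCurve",
    "TortuosityVector",
    "BifurcationMetrics",
    "FractalDims",
    "resample_and_curvature",
    "tortuosity_metrics",
    "bifurcation_metrics",
    "endpoint_direction",
    "fractal_dimensions",
    "TORTUOSITY_NAMES",
    "BIFURCATION_NAMES",
]

TORTUOSITY_NAMES = tuple(f"tau{i}" for i in range(1, 15))
BIFURCATION_NAMES = ("d0", "d1", "d2", "alpha", "beta", "lam", "lam1", "lam2",
                     "theta1", "theta2", "theta")


@dataclass
class CenterlineCurve:
    """A uniformly arc-length-resampled centerline with curvature profile."""

    points: np.ndarray          # (n, 2) resampled (x, y)
    spacing: float              # px between consecutive samples
    arc_length: float           # L_a, px
    chord_length: float         # L_c, px
    kappa: np.ndarray           # signed curvature per sample, 1/px
    smooth: float               # smoothing used (px RMS)

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class TortuosityVector:
    """The 14 tortuosity metrics of one segment.

    tau1   arc/chord ratio (≥ 1, dimensionless)
    tau2   arc/chord ratio − 1
    tau3   total curvature ∫|κ| ds (radians)
    tau4   total squared curvature ∫κ² ds (1/px)
    tau5   tau3 / arc length (1/px)
    tau6   tau4 / arc length (1/px²)
    tau7   tau3 / chord length (1/px)
    tau8   tau4 / chord length (1/px²)
    tau9   integrated curvature: Σ|turn angle| along the polyline (radians)
    tau10  smooth tortuosity index: arc/chord of the strongly smoothed curve
    tau11  CAIAR tortuosity index: mean κ² over samples (1/px²)
    tau12  tortuosity coefficient 01: (n_inflections + 1)·tau2
    tau13  tortuosity coefficient 02: (n_inflections + 1)·tau3 / chord (1/px)
    tau14  SD tortuosity: standard deviation of signed κ (1/px)

    The literature gives tau10–tau13 by name only; the operational formulas
    above are this package's documented interpretation.
    """

    values: dict = field(default_factory=dict)

    def __getattr__(self, name):
        try:
            return self.values[name]
        except KeyError:  # pragma: no cover
            raise AttributeError(name)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in TORTUOSITY_NAMES])


@dataclass
class BifurcationMetrics:
    """Optimality metrics of one junction (widths in consistent units).

    With parent width d0 and daughter widths d1 ≥ d2:
    alpha = (d2/d1)² (asymmetry ratio), beta = (d1²+d2²)/d0² (area ratio),
    lam = d2/d1 (bifurcation index), lam1 = d1/d0, lam2 = d2/d0;
    theta1/theta2 are the daughters' angles from the parent's continuation
    (degrees) and theta = theta1 + theta2.
    """

    d0: float
    d1: float
    d2: float
    alpha: float
    beta: float
    lam: float
    lam1: float
    lam2: float
    theta1: float
    theta2: float
    theta: float

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in BIFURCATION_NAMES}


@dataclass
class FractalDims:
    """Box (D_B), information (D_I) and correlation (D_C) dimensions."""

    D_B: float
    D_I: float
    D_C: float
    r_squared: dict
    scales_px: np.ndarray


# ---------------------------------------------------------------------------
# Curvature
# ---------------------------------------------------------------------------

def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R²; a constant y gives slope 0, R² 1."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(y) < 1e-12:
        return 0.0, 1.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return float(slope), float(r2)


def resample_and_curvature(
    polyline: np.ndarray,
    spacing: float = 1.0,
    smooth: float = 0.0,
) -> CenterlineCurve:
    """Smooth, resample to uniform arc length, and compute signed curvature.

    A parametric cubic smoothing spline is fitted to the polyline (FITPACK
    residual budget ``n·smooth²``, i.e. ``smooth`` is the tolerated RMS
    deviation in px).  The spline is resampled at uniform arc-length steps of
    approximately ``spacing`` px and the signed curvature

        κ = (x′y″ − y′x″) / (x′² + y′²)^{3/2}

    is evaluated from the analytic spline derivatives.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("polyline must be an (n≥2, 2) array")
    step = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(step == 0):
        raise ValueError("polyline contains repeated consecutive points")
    u = np.concatenate([[0.0], np.cumsum(step)])
    total_chord = u[-1]
    if total_chord <= 0:
        raise ValueError("zero-length polyline")
    u /= total_chord

    k = min(3, len(pts) - 1)
    s = len(pts) * smooth**2
    tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], u=u, k=k, s=s)

    # dense arc-length table to invert s(u)
    u_dense = np.linspace(0.0, 1.0, max(20 * len(pts), 1000))
    dx, dy = interpolate.splev(u_dense, tck, der=1)
    speed = np.hypot(dx, dy)
    s_dense = cumulative_trapezoid(speed, u_dense, initial=0.0)
    arc_length = float(s_dense[-1])

    n_samples = max(int(round(arc_length / spacing)) + 1, 3)
    s_targets = np.linspace(0.0, arc_length, n_samples)
    u_samples = np.interp(s_targets, s_dense, u_dense)

    x, y = interpolate.splev(u_samples, tck, der=0)
    x1, y1 = interpolate.splev(u_samples, tck, der=1)
    if k >= 2:
        x2, y2 = interpolate.splev(u_samples, tck, der=2)
    else:
        x2 = np.zeros_like(x1)
        y2 = np.zeros_like(y1)
    denom = (x1**2 + y1**2) ** 1.5
    kappa = np.where(denom > 0, (x1 * y2 - y1 * x2) / np.where(denom > 0, denom, 1.0), 0.0)

    points = np.column_stack([x, y])
    chord = float(np.linalg.norm(points[-1] - points[0]))
    if chord <= 0:
        raise ValueError("closed or degenerate centerline (zero chord)")
    return CenterlineCurve(
        points=points,
        spacing=float(s_targets[1] - s_targets[0]),
        arc_length=arc_length,
        chord_length=chord,
        kappa=np.asarray(kappa, float),
        smooth=smooth,
    )


def _count_inflections(kappa: np.ndarray) -> int:
    """Sign changes of the curvature profile, with a relative dead band.

    Samples with |κ| below 1e-3 of the profile maximum are treated as holding
    the previous sign, so numerical jitter on near-straight stretches does
    not create spurious inflections.
    """
    peak = np.max(np.abs(kappa)) if len(kappa) else 0.0
    if peak < 1e-9:
        return 0
    band = 1e-3 * peak
    signs = np.sign(kappa)
    signs[np.abs(kappa) < band] = 0
    last = 0
    flips = 0
    for s in signs:
        if s == 0:
            continue
        if last != 0 and s != last:
            flips += 1
        last = s
    return flips


def tortuosity_metrics(
    curve: CenterlineCurve,
    smooth_index_rms: float = 2.0,
) -> TortuosityVector:
    """Compute the 14 tortuosity metrics of a resampled centerline.

    ``smooth_index_rms`` is the spline smoothing (px RMS) used for the
    smooth-tortuosity index tau10, which measures arc/chord of a strongly
    smoothed version of the curve.
    """
    la, lc = curve.arc_length, curve.chord_length
    kappa = curve.kappa
    abs_k = np.abs(kappa)
    tau1 = la / lc
    tau2 = tau1 - 1.0
    # integrals over arc length (uniform spacing -> trapezoid)
    tau3 = float(np.trapezoid(abs_k, dx=curve.spacing))
    tau4 = float(np.trapezoid(kappa**2, dx=curve.spacing))

    # turn angles of the resampled polyline
    d = np.diff(curve.points, axis=0)
    ang = np.arctan2(d[:, 1], d[:, 0])
    turn = np.diff(ang)
    turn = (turn + np.pi) % (2 * np.pi) - np.pi
    tau9 = float(np.sum(np.abs(turn)))

    smoothed = resample_and_curvature(
        curve.points, spacing=curve.spacing, smooth=smooth_index_rms
    )
    tau10 = smoothed.arc_length / smoothed.chord_length

    n_inf = _count_inflections(kappa)
    vals = {
        "tau1": tau1,
        "tau2": tau2,
        "tau3": tau3,
        "tau4": tau4,
        "tau5": tau3 / la,
        "tau6": tau4 / la,
        "tau7": tau3 / lc,
        "tau8": tau4 / lc,
        "tau9": tau9,
        "tau10": tau10,
        "tau11": float(np.mean(kappa**2)),
        "tau12": (n_inf + 1) * tau2,
        "tau13": (n_inf + 1) * tau3 / lc,
        "tau14": float(np.std(kappa)),
    }
    return TortuosityVector(values=vals)


# ---------------------------------------------------------------------------
# Bifurcations
# ---------------------------------------------------------------------------

def endpoint_direction(polyline: np.ndarray, end: str, n: int = 5) -> np.ndarray:
    """Unit direction of a polyline at one end, averaged over ``n`` points.

    ``end='last'`` gives the outgoing direction at the final point (flow
    direction of a parent arriving at a junction); ``end='first'`` gives the
    outgoing direction at the initial point (a daughter leaving a junction).
    Using several points makes the estimate robust to click jitter.
    """
    pts = np.asarray(polyline, float)
    n = min(n, len(pts))
    if end == "last":
        v = pts[-1] - pts[-n]
    elif end == "first":
        v = pts[n - 1] - pts[0]
    else:
        raise ValueError("end must be 'first' or 'last'")
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero-length direction")
    return v / norm


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length direction vector")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def bifurcation_metrics(
    d0: float,
    d1: float,
    d2: float,
    dir0: np.ndarray,
    dir1: np.ndarray,
    dir2: np.ndarray,
) -> BifurcationMetrics:
    """Geometric optimality metrics at one junction.

    ``d0`` is the parent width, ``d1``/``d2`` the daughter widths (any
    order; they are relabelled so d1 ≥ d2, making alpha and lam lie in
    (0, 1]).  ``dir0`` is the parent's flow direction entering the junction
    and ``dir1``/``dir2`` the daughters' outgoing directions; branch angles
    are measured against the parent direction continued through the junction,
    and theta = theta1 + theta2 by construction.
    """
    if min(d0, d1, d2) <= 0:
        raise ValueError("all widths must be positive")
    if d1 < d2:
        d1, d2 = d2, d1
        dir1, dir2 = dir2, dir1
    theta1 = _angle_deg(dir1, dir0)
    theta2 = _angle_deg(dir2, dir0)
    return BifurcationMetrics(
        d0=d0, d1=d1, d2=d2,
        alpha=(d2 / d1) ** 2,
        beta=(d1**2 + d2**2) / d0**2,
        lam=d2 / d1,
        lam1=d1 / d0,
        lam2=d2 / d0,
        theta1=theta1,
        theta2=theta2,
        theta=theta1 + theta2,
    )


# ---------------------------------------------------------------------------
# Fractal dimensions
# ---------------------------------------------------------------------------

def fractal_dimensions(
    points: np.ndarray,
    image_size: tuple[int, int],
    n_scales: int = 8,
    min_occupied: int = 5,
) -> FractalDims:
    """Box, information and correlation dimensions of a planar point set.

    Dyadic box sizes ε = 2, 4, 8, … px up to min(image_size)/4 (at most
    ``n_scales`` of them) are laid on a grid anchored at the point cloud's
    bounding box.  D_B is the least-squares slope of log N(ε) against
    log(1/ε); D_I the slope of Σ pᵢ log pᵢ against log ε (pᵢ the occupancy
    fraction of box i); D_C the Grassberger–Procaccia slope of log C(ε)
    against log ε with C(ε) the fraction of point pairs closer than ε.
    Scales occupying fewer than ``min_occupied`` boxes are dropped from the
    box/information regressions to avoid saturation bias at coarse scales
    (all scales are kept if fewer than two survive).
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 100:
        raise ValueError("need at least 100 points for a stable estimate")
    if n_scales < 4:
        raise ValueError("need at least 4 scales")

    max_eps = min(image_size) / 4.0
    scales = [2.0 * 2**i for i in range(n_scales) if 2.0 * 2**i <= max_eps]
    if len(scales) < 4:
        raise ValueError("image too small for 4 dyadic scales")
    scales = np.array(scales)

    origin = pts.min(axis=0)
    n_boxes = np.empty(len(scales))
    plogp = np.empty(len(scales))
    for i, eps in enumerate(scales):
        idx = np.floor((pts - origin) / eps).astype(np.int64)
        _, counts = np.unique(idx, axis=0, return_counts=True)
        n_boxes[i] = len(counts)
        p = counts / len(pts)
        plogp[i] = float(np.sum(p * np.log(p)))

    keep = n_boxes >= min_occupied
    if keep.sum() < 2:
        keep = np.ones(len(scales), bool)
    d_b, r2_b = _ols_slope(np.log(1.0 / scales[keep]), np.log(n_boxes[keep]))
    d_i, r2_i = _ols_slope(np.log(scales[keep]), plogp[keep])

    tree = cKDTree(pts)
    n = len(pts)
    pair_counts = tree.count_neighbors(tree, scales) - n  # remove self-pairs
    corr = pair_counts / (n * (n - 1.0))
    pos = corr > 0
    if pos.sum() >= 2 and np.ptp(np.log(corr[pos])) > 1e-12:
        d_c, r2_c = _ols_slope(np.log(scales[pos]), np.log(corr[pos]))
    else:
        d_c, r2_c = 0.0, 1.0

    return FractalDims(
        D_B=d_b,
        D_I=d_i,
        D_C=d_c,
        r_squared={"D_B": r2_b, "D_I": r2_i, "D_C": r2_c},
        scales_px=scales,
    )
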