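"""Synthetic ground-truth generators for every pipeline input.

No clinical data ships with this package; instead this module fabricates the
four inputs the pipeline consumes, with known ground truth:

* branching vessel trees whose radii obey Murray's law and whose centerline
  arc length, chord length, curvature and junction angles are recorded,
* fundus-like RGB rasters with Gaussian-profile vessels (FWHM = true width),
  a bright optic-disc ellipse, and additive Gaussian noise,
* cohorts of subjects whose per-image biomarker vectors carry planted,
  recoverable effects of a latent coronary-disease severity that also drives
  the CAD-RADS score through ordered thresholds.

All randomness flows from explicit integer seeds; identical seeds reproduce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit
from scipy.stats import norm

from .tracing import AnnotationSet, SubjectRecord, VesselSegment, assign_cat, binarize_cadrads

__all__ = [
    "TruthSegment",
    "TruthJunction",
    "VesselTreeTruth",
    "CohortSpec",
    "generate_vessel_tree",
    "rasterize_fundus",
    "generate_cohort",
    "generate_homophily_cohort",
    "tree_to_annotation_set",
    "DEFAULT_PLANTED_EFFECTS",
]


@dataclass
class TruthSegment:
    id: int
    polyline: np.ndarray  # (n, 2) (x, y) px
    width_px: float
    vessel_type: str
    parent_id: int  # -1 for root
    arc_length: float
    chord_length: float


@dataclass
class TruthJunction:
    id: int
    parent_segment: int
    d0: float
    d1: float
    d2: float
    theta1_deg: float
    theta2_deg: float
    vessel_type: str

    @property
    def theta_deg(self) -> float:
        return self.theta1_deg + self.theta2_deg


@dataclass
class VesselTreeTruth:
    segments: list[TruthSegment]
    junctions: list[TruthJunction]
    optic_disc: dict  # center (x, y), semi-axes (a, b) px, rotation deg
    image_size: tuple[int, int]  # (H, W)


def _sinusoid_polyline(
    p0: np.ndarray, direction: np.ndarray, length: float, amp: float, n: int
) -> np.ndarray:
    """Centerline from p0 along ``direction``: straight path plus one full
    sine period of lateral amplitude ``amp`` px (amp 0 -> exactly straight)."""
    t = np.linspace(0.0, 1.0, n)
    normal = np.array([-direction[1], direction[0]])
    pts = (
        p0[None, :]
        + t[:, None] * length * direction[None, :]
        + (amp * np.sin(2 * np.pi * t))[:, None] * normal[None, :]
    )
    return pts


def _rot(v: np.ndarray, deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def generate_vessel_tree(
    branching_depth: int,
    root_width: float,
    tortuosity_amp: float,
    seed: int,
    *,
    image_size: tuple[int, int] = (480, 640),
    vessel_type: str = "artery",
    lambda_range: tuple[float, float] = (0.7, 1.0),
    total_angle_range: tuple[float, float] = (30.0, 90.0),
    root_length: float = 150.0,
    length_decay: float = 0.72,
    start: tuple[float, float] | None = None,
    start_direction_deg: float | None = None,
) -> VesselTreeTruth:
    """Grow a binary vessel tree with Murray-law radii and recorded truth.

    At every junction the parent width d0 splits into daughters satisfying
    d0³ = d1³ + d2³ exactly, with the bifurcation index λ = d2/d1 drawn
    uniformly from ``lambda_range`` (set it to (1, 1) for symmetric splits).
    The total branch angle is uniform over ``total_angle_range`` degrees and
    its asymmetric split over the two daughters is recorded as ground truth.
    Centerlines are straight paths with a sinusoidal lateral perturbation
    scaled by ``tortuosity_amp`` (0 gives exactly straight segments).
    """
    if branching_depth < 1:
        raise ValueError("branching_depth must be >= 1")
    if root_width < 3:
        raise ValueError("root_width below 3 px: width measurement unreliable")
    if vessel_type not in ("artery", "vein"):
        raise ValueError("vessel_type must be artery or vein")
    rng = np.random.default_rng(seed)
    h, w = image_size
    margin = 12.0

    disc_center = np.array([60.0, h / 2.0])
    disc = {
        "center": (float(disc_center[0]), float(disc_center[1])),
        "a": 45.0,
        "b": 40.0,
        "rotation_deg": float(rng.uniform(0, 180)),
    }
    if start is None:
        start = disc_center + np.array([disc["a"], 0.0])
    p0 = np.asarray(start, float)
    if start_direction_deg is None:
        start_direction_deg = float(rng.uniform(-25, 25))
    d0_dir = _rot(np.array([1.0, 0.0]), start_direction_deg)

    segments: list[TruthSegment] = []
    junctions: list[TruthJunction] = []
    next_id = [0]

    def grow(p: np.ndarray, direction: np.ndarray, width: float, length: float,
             depth: int, parent: int) -> None:
        # steer back toward the interior if the endpoint would leave bounds
        for _ in range(8):
            end = p + length * direction
            if margin <= end[0] <= w - margin and margin <= end[1] <= h - margin:
                break
            to_center = np.array([w / 2, h / 2]) - p
            to_center /= np.linalg.norm(to_center)
            direction = 0.6 * direction + 0.4 * to_center
            direction /= np.linalg.norm(direction)
        amp = tortuosity_amp * length / 12.0
        n_pts = max(int(length), 16)
        poly = _sinusoid_polyline(p, direction, length, amp, n_pts)
        poly[:, 0] = np.clip(poly[:, 0], 2.0, w - 3.0)
        poly[:, 1] = np.clip(poly[:, 1], 2.0, h - 3.0)
        arc = float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))
        chord = float(np.linalg.norm(poly[-1] - poly[0]))
        seg_id = next_id[0]
        next_id[0] += 1
        segments.append(
            TruthSegment(seg_id, poly, width, vessel_type, parent, arc, chord)
        )
        if depth > branching_depth or width < 2.0:
            return
        lam = float(rng.uniform(*lambda_range))
        d1 = width / (1.0 + lam**3) ** (1.0 / 3.0)
        d2 = lam * d1
        theta = float(rng.uniform(*total_angle_range))
        frac = float(rng.uniform(0.35, 0.65))
        theta1, theta2 = frac * theta, (1 - frac) * theta
        end_dir = poly[-1] - poly[-2]
        end_dir = end_dir / np.linalg.norm(end_dir)
        side = 1.0 if rng.uniform() < 0.5 else -1.0
        dir1 = _rot(end_dir, side * theta1)
        dir2 = _rot(end_dir, -side * theta2)
        junctions.append(
            TruthJunction(len(junctions), seg_id, width, d1, d2, theta1, theta2,
                          vessel_type)
        )
        child_len = length * length_decay
        grow(poly[-1].copy(), dir1, d1, child_len, depth + 1, seg_id)
        grow(poly[-1].copy(), dir2, d2, child_len, depth + 1, seg_id)

    grow(p0, d0_dir, float(root_width), root_length, 1, -1)
    return VesselTreeTruth(segments, junctions, disc, image_size)


def tree_to_annotation_set(tree: VesselTreeTruth, image_id: str | None = None) -> AnnotationSet:
    """Convert ground truth into the tracing data model (drops widths)."""
    segs = [
        VesselSegment(s.id, s.polyline.copy(), s.vessel_type, s.parent_id)
        for s in tree.segments
    ]
    return AnnotationSet(segments=segs, image_size=tree.image_size, image_id=image_id)


FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def rasterize_fundus(
    tree: VesselTreeTruth,
    background_level: float = 0.55,
    noise_sd: float = 0.02,
    seed: int = 0,
    vessel_contrast: float = 0.25,
    disc_brightness: float = 0.25,
) -> np.ndarray:
    """Render a tree as a fundus-like RGB uint8 image.

    Vessels are darker than background in the green channel, with a Gaussian
    cross-section whose FWHM equals the true width; the optic disc is a
    bright ellipse; i.i.d. Gaussian noise of ``noise_sd`` (intensity units,
    image scale [0, 1]) is added per channel.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    h, w = tree.image_size
    rng = np.random.default_rng(seed)
    dip = np.zeros((h, w), float)

    yy, xx = np.mgrid[0:h, 0:w]
    for seg in tree.segments:
        if seg.width_px < 1:
            raise ValueError("cannot rasterize widths below 1 px")
        sigma = seg.width_px * FWHM_TO_SIGMA
        reach = 3.0 * sigma + 2.0
        # densify the centerline so the distance field is smooth
        d = np.diff(seg.polyline, axis=0)
        step = np.linalg.norm(d, axis=1)
        n_dense = max(int(step.sum() / 0.25), len(seg.polyline))
        t = np.linspace(0, 1, len(seg.polyline))
        td = np.linspace(0, 1, n_dense)
        dense = np.column_stack(
            [np.interp(td, t, seg.polyline[:, 0]), np.interp(td, t, seg.polyline[:, 1])]
        )
        x0 = max(int(dense[:, 0].min() - reach), 0)
        x1 = min(int(dense[:, 0].max() + reach) + 1, w)
        y0 = max(int(dense[:, 1].min() - reach), 0)
        y1 = min(int(dense[:, 1].max() + reach) + 1, h)
        if x1 <= x0 or y1 <= y0:
            continue
        sub = np.column_stack(
            [xx[y0:y1, x0:x1].ravel(), yy[y0:y1, x0:x1].ravel()]
        ).astype(float)
        dist, _ = cKDTree(dense).query(sub, k=1)
        prof = vessel_contrast * np.exp(-(dist**2) / (2 * sigma**2))
        patch = prof.reshape(y1 - y0, x1 - x0)
        np.maximum(dip[y0:y1, x0:x1], patch, out=dip[y0:y1, x0:x1])

    # optic disc: smooth bright ellipse
    cx, cy = tree.optic_disc["center"]
    a, b = tree.optic_disc["a"], tree.optic_disc["b"]
    phi = np.radians(tree.optic_disc["rotation_deg"])
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    q = (u / a) ** 2 + (v / b) ** 2
    disc_glow = disc_brightness * expit(-(q - 1.0) * 8.0)

    green = background_level - dip + disc_glow
    red = np.clip(green * 1.55, 0, 1)
    blue = np.clip(green * 0.45, 0, 1)
    img = np.stack([red, green, blue], axis=-1)
    img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Standardized mean shift per unit latent severity planted by default:
#: narrower arteries, wider branch angles, lower fractal dimension with
#: increasing coronary disease severity.
DEFAULT_PLANTED_EFFECTS = {
    "artery_width_mean": -0.8,
    "artery_theta_mean": 0.8,
    "vein_theta_mean": 0.8,
    "artery_D_B": -0.8,
    "vein_D_B": -0.8,
}

# Cohort moments mirroring the study population (overall column of the
# demographics table): n=145, 78 with both eyes, CAD-RADS counts 55/15/37/20/13/5.
_DEFAULT_CADRADS_PROBS = tuple(np.array([55, 15, 37, 20, 13, 5]) / 145.0)


@dataclass
class CohortSpec:
    """Study-condition parameters for the synthetic cohort generator."""

    n_subjects: int = 145
    age_mean: float = 58.5
    age_sd: float = 12.0
    age_bounds: tuple[float, float] = (30.0, 90.0)
    male_fraction: float = 0.58
    cadrads_probs: tuple = _DEFAULT_CADRADS_PROBS
    effects: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED_EFFECTS))
    both_eyes_p: float = 78.0 / 145.0
    eye_rho: float = 0.7
    noise_sd: float = 1.0
    seed: int = 0
    age_severity_corr: float = 0.45
    gender_severity_beta: float = 0.5

    def validate(self, schema_names: list[str]) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 <= self.both_eyes_p <= 1.0:
            raise ValueError("both_eyes_p must be in [0, 1]")
        p = np.asarray(self.cadrads_probs, float)
        if len(p) != 6 or abs(p.sum() - 1.0) > 1e-8 or np.any(p < 0):
            raise ValueError("cadrads_probs must be 6 nonnegative values summing to 1")
        unknown = sorted(set(self.effects) - set(schema_names))
        if unknown:
            raise ValueError(f"planted-effect features not in schema: {unknown}")


def generate_cohort(
    spec: CohortSpec, schema_names: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw a labelled cohort with planted biomarker effects.

    A latent severity s ~ N(0,1) per subject determines the CAD-RADS score
    through ordered thresholds placed at the quantiles of ``cadrads_probs``
    (an ordered-probit mapping preserving the score's ordinal structure).
    Per-image biomarker vectors are multivariate normal; features named in
    ``spec.effects`` have mean shifted by effect·s standard deviations.
    The two eyes of one subject are correlated with ρ = ``eye_rho``.

    Returns ``(cohort, features, truth)``: one row per subject, one row per
    image, and the ground-truth latent severities / thresholds / effects.
    """
    if schema_names is None:
        from .features import default_schema
        schema_names = default_schema().names
    spec.validate(schema_names)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    s = rng.normal(size=n)  # latent severity
    cum = np.cumsum(spec.cadrads_probs)[:-1]
    thresholds = norm.ppf(cum)
    cadrads = np.sum(s[:, None] > thresholds[None, :], axis=1).astype(int)

    r = spec.age_severity_corr
    age = spec.age_mean + spec.age_sd * (r * s + np.sqrt(1 - r**2) * rng.normal(size=n))
    age = np.clip(age, *spec.age_bounds)
    logit_m = np.log(spec.male_fraction / (1 - spec.male_fraction))
    p_male = 1 / (1 + np.exp(-(logit_m + spec.gender_severity_beta * s)))
    male = rng.uniform(size=n) < p_male

    # cardiovascular covariates for adjusted association models
    bmi = np.clip(25.3 + 4.7 * (0.1 * s + rng.normal(size=n)), 15, 45)
    sbp = 131.0 + 18.5 * rng.normal(size=n)
    dbp = 80.0 + 11.6 * rng.normal(size=n)
    heart_rate = 72.4 + 11.7 * (-0.13 * s + rng.normal(size=n))
    diabetes = rng.uniform(size=n) < 1 / (1 + np.exp(-(-1.7 + 0.25 * s)))
    smoker = rng.uniform(size=n) < 0.10
    prior_stent = rng.uniform(size=n) < 1 / (1 + np.exp(-(-3.2 + 0.9 * s)))
    prior_cabg = rng.uniform(size=n) < 1 / (1 + np.exp(-(-4.0 + 0.9 * s)))
    scheduled = rng.uniform(size=n) < 1 / (1 + np.exp(-(-3.5 + 0.9 * s)))

    rows = []
    image_rows = []
    feat_rows = []
    d = len(schema_names)
    effect_vec = np.zeros(d)
    for name, e in spec.effects.items():
        effect_vec[schema_names.index(name)] = e

    for i in range(n):
        sid = f"S{i:04d}"
        if rng.uniform() < spec.both_eyes_p:
            eyes = ["L", "R"]
        else:
            eyes = [rng.choice(["L", "R"])]
        rec = SubjectRecord(
            subject_id=sid,
            age=float(age[i]),
            gender="male" if male[i] else "female",
            cadrads=int(cadrads[i]),
            prior_stent=bool(prior_stent[i]),
            prior_cabg=bool(prior_cabg[i]),
            scheduled_intervention=bool(scheduled[i]),
            eyes=tuple(f"{sid}_{e}" for e in eyes),
        )
        rows.append({
            "subject_id": sid,
            "age": rec.age,
            "gender": rec.gender,
            "cadrads": rec.cadrads,
            "prior_stent": rec.prior_stent,
            "prior_cabg": rec.prior_cabg,
            "scheduled_intervention": rec.scheduled_intervention,
            "quality_ok": True,
            "bmi": float(bmi[i]),
            "sbp": float(sbp[i]),
            "dbp": float(dbp[i]),
            "heart_rate": float(heart_rate[i]),
            "diabetes": bool(diabetes[i]),
            "smoker": bool(smoker[i]),
            "label_model1": binarize_cadrads(rec.cadrads),
            "label_model2": assign_cat(rec),
        })
        z_subj = rng.normal(size=d)
        for eye in eyes:
            z_eye = (
                np.sqrt(spec.eye_rho) * z_subj
                + np.sqrt(1 - spec.eye_rho) * rng.normal(size=d)
            )
            feats = spec.noise_sd * z_eye + effect_vec * s[i]
            image_rows.append({"image_id": f"{sid}_{eye}", "subject_id": sid, "eye": eye})
            feat_rows.append(feats)

    cohort = pd.DataFrame(rows)
    features = pd.concat(
        [
            pd.DataFrame(image_rows),
            pd.DataFrame(np.array(feat_rows), columns=schema_names),
        ],
        axis=1,
    )
    truth = {
        "severity": s,
        "thresholds": thresholds,
        "effects": dict(spec.effects),
        "schema_names": list(schema_names),
    }
    return cohort, features, truth


def generate_homophily_cohort(
    n_subjects: int = 180,
    seed: int = 0,
    n_features: int = 20,
    n_informative: int = 5,
    own_signal: float = 0.10,
    age_slope: float = 0.017,
    gender_shift: float = 0.22,
    both_eyes_p: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort where the label follows the demographic neighbourhood.

    The class probability rises with age and is higher for men —
    ``p = clip(0.08 + age_slope·(age − 35), 0.08, 0.85) ± gender_shift`` —
    the qualitative pattern of coronary-disease cohorts.  Because the
    population-graph rule links images of same-gender or age-matched
    subjects, a node's neighbourhood majority is then strongly informative
    about its label, while its own image features carry only a weak signal
    (``own_signal`` SD on ``n_informative`` of ``n_features`` features).
    This is the regime in which neighbourhood aggregation should beat a
    plain logistic model on the node's own features.

    Returns ``(cohort, features)`` with a ``label`` column on both.
    """
    rng = np.random.default_rng(seed)
    rows, image_rows, feat_rows = [], [], []
    for i in range(n_subjects):
        sid = f"H{i:04d}"
        age = float(rng.uniform(35.0, 85.0))
        gender = "male" if rng.uniform() < 0.5 else "female"
        p = np.clip(0.08 + age_slope * (age - 35.0), 0.08, 0.85)
        p = np.clip(p + (gender_shift if gender == "male" else -gender_shift),
                    0.03, 0.97)
        label = int(rng.uniform() < p)
        rows.append({
            "subject_id": sid,
            "age": age,
            "gender": gender,
            "label": label,
        })
        eyes = ["L", "R"] if rng.uniform() < both_eyes_p else [rng.choice(["L", "R"])]
        for eye in eyes:
            z = rng.normal(size=n_features)
            z[:n_informative] += own_signal * (2 * label - 1)
            image_rows.append({
                "image_id": f"{sid}_{eye}", "subject_id": sid, "eye": eye,
                "label": label,
            })
            feat_rows.append(z)
    cohort = pd.DataFrame(rows)
    features = pd.concat(
        [
            pd.DataFrame(image_rows),
            pd.DataFrame(np.array(feat_rows),
                         columns=[f"f{j}" for j in range(n_features)]),
        ],
        axis=1,
    )
    return cohort, features
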