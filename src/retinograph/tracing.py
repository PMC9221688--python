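"""Vessel-tracing I/O, optic-disc geometry, pixel calibration and class labels.

The centerline tracings follow the NeuronJ convention: each vessel segment is a
polyline with a type name (``axon`` for arteries, ``dendrite`` for veins) and a
parent label; a segment whose parent is outside the image, or which originates
at the optic disc, carries the parent label ``N0`` (root).

Because the full NeuronJ ``.ndf`` format is versioned and under-documented,
this package defines a minimal text dialect that carries exactly the fields
the pipeline needs.  Files written by :func:`write_ndf` round-trip through
:func:`read_ndf` bit-identically.

NDF dialect
-----------
::

    # retinograph-ndf 1
    # image_size <H> <W>          (optional)
    T <id> <axon|dendrite> <parent label: N0 or integer id>
    <x> <y>
    <x> <y>
    ...
    (blank line or next ``T`` line ends the block)

Coordinates are 0-based pixel centers, ``x`` = column, ``y`` = row; polylines
are open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.measure import EllipseModel

ROOT = -1
"""Sentinel parent id for segments whose parent is the optic disc / off-image."""

OPTIC_DISC_DIAMETER_UM = 1800.0
"""Conventional optic-disc diameter used for pixel-size calibration (µm)."""

_TYPE_TO_VESSEL = {"axon": "artery", "dendrite": "vein"}
_VESSEL_TO_TYPE = {v: k for k, v in _TYPE_TO_VESSEL.items()}

HEADER = "# retinograph-ndf 1"


class NdfError(ValueError):
    """Raised on malformed tracing files."""


@dataclass
class VesselSegment:
    """A traced centerline of one vessel segment."""

    id: int
    polyline: np.ndarray  # (n, 2) float array of (x, y) pixel coords
    vessel_type: str  # "artery" | "vein"
    parent_id: int = ROOT

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 2:
            raise NdfError(f"segment {self.id}: polyline must be (n, 2)")
        if len(self.polyline) < 2:
            raise NdfError(f"segment {self.id}: degenerate tracing (<2 points)")
        if np.any(np.all(np.diff(self.polyline, axis=0) == 0, axis=1)):
            raise NdfError(f"segment {self.id}: repeated consecutive points")
        if self.vessel_type not in ("artery", "vein"):
            raise NdfError(f"segment {self.id}: unknown vessel type {self.vessel_type!r}")

    @property
    def is_root(self) -> bool:
        return self.parent_id == ROOT


@dataclass
class OpticDisc:
    """Fitted optic-disc ellipse and the pixel calibration derived from it."""

    clicked_points: np.ndarray  # (6, 2)
    center: tuple[float, float]
    a: float  # semi-major axis, px
    b: float  # semi-minor axis, px
    rotation_deg: float
    residual_rms: float

    @property
    def pixel_size_um(self) -> float:
        return pixel_size(self)


@dataclass
class AnnotationSet:
    """All traced segments of one fundus image plus disc geometry."""

    segments: list[VesselSegment]
    optic_disc: OpticDisc | None = None
    image_size: tuple[int, int] | None = None  # (H, W)
    image_id: str | None = None

    def by_type(self, vessel_type: str) -> list[VesselSegment]:
        return [s for s in self.segments if s.vessel_type == vessel_type]

    @property
    def pixel_size_um(self) -> float | None:
        return None if self.optic_disc is None else self.optic_disc.pixel_size_um


@dataclass
class SubjectRecord:
    """Demographics and clinical flags of one subject."""

    subject_id: str
    age: float
    gender: str  # "male" | "female"
    cadrads: int
    prior_stent: bool = False
    prior_cabg: bool = False
    scheduled_intervention: bool = False
    eyes: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.gender not in ("male", "female"):
            raise ValueError(f"gender must be male/female, got {self.gender!r}")
        if self.cadrads not in range(6):
            raise ValueError(f"CAD-RADS score must be in 0..5, got {self.cadrads}")


# ---------------------------------------------------------------------------
# NDF I/O
# ---------------------------------------------------------------------------

def read_ndf(path: str | Path) -> AnnotationSet:
    """Parse a tracing file in the package's NDF dialect.

    NeuronJ type names map to vessel types (axon → artery, dendrite → vein)
    and the parent label ``N0`` maps to :data:`ROOT`.  Unknown type names and
    dangling parent references are rejected.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines or lines[0].strip() != HEADER:
        raise NdfError(f"{path}: missing dialect header {HEADER!r}")

    image_size: tuple[int, int] | None = None
    raw: list[tuple[int, str, str, list[tuple[float, float]], int]] = []
    current: tuple[int, str, str, list[tuple[float, float]], int] | None = None

    for lineno, line in enumerate(lines[1:], start=2):
        stripped = line.strip()
        if stripped.startswith("# image_size"):
            parts = stripped.split()
            image_size = (int(parts[2]), int(parts[3]))
            continue
        if stripped.startswith("#"):
            continue
        if not stripped:
            if current is not None:
                raw.append(current)
                current = None
            continue
        if stripped.startswith("T "):
            if current is not None:
                raw.append(current)
            parts = stripped.split()
            if len(parts) != 4:
                raise NdfError(f"{path}:{lineno}: malformed tracing header {stripped!r}")
            seg_id, type_name, parent_label = int(parts[1]), parts[2], parts[3]
            if type_name not in _TYPE_TO_VESSEL:
                raise NdfError(
                    f"{path}:{lineno}: unknown type name {type_name!r} "
                    f"(expected one of {sorted(_TYPE_TO_VESSEL)})"
                )
            current = (seg_id, type_name, parent_label, [], lineno)
            continue
        if current is None:
            raise NdfError(f"{path}:{lineno}: point outside a tracing block")
        xy = stripped.split()
        current[3].append((float(xy[0]), float(xy[1])))
    if current is not None:
        raw.append(current)

    segments: list[VesselSegment] = []
    ids = {seg_id for seg_id, *_ in raw}
    orphans = []
    for seg_id, type_name, parent_label, pts, lineno in raw:
        if len(pts) < 2:
            raise NdfError(f"{path}:{lineno}: tracing {seg_id} is degenerate (<2 points)")
        if parent_label == "N0":
            parent_id = ROOT
        else:
            parent_id = int(parent_label)
            if parent_id not in ids:
                orphans.append(seg_id)
        segments.append(
            VesselSegment(seg_id, np.array(pts), _TYPE_TO_VESSEL[type_name], parent_id)
        )
    if orphans:
        raise NdfError(f"{path}: dangling parent references for segments {orphans}")
    return AnnotationSet(segments=segments, image_size=image_size, image_id=path.stem)


def write_ndf(annotations: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` in the NDF dialect (read_ndf inverse)."""
    buf = io.StringIO()
    buf.write(HEADER + "\n")
    if annotations.image_size is not None:
        h, w = annotations.image_size
        buf.write(f"# image_size {h} {w}\n")
    for seg in annotations.segments:
        parent = "N0" if seg.is_root else str(seg.parent_id)
        buf.write(f"T {seg.id} {_VESSEL_TO_TYPE[seg.vessel_type]} {parent}\n")
        for x, y in seg.polyline:
            buf.write(f"{x:.6g} {y:.6g}\n")
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Optic disc and calibration
# ---------------------------------------------------------------------------

def fit_optic_disc(points: np.ndarray) -> OpticDisc:
    """Fit a rotated ellipse to six clicked optic-disc boundary points.

    Uses the direct (non-iterative) least-squares conic fit constrained to an
    ellipse.  Six points is one more than the conic minimum, so the fit is
    near-interpolating; the residual RMS is reported for quality control.
    """
    points = np.asarray(points, dtype=float)
    if points.shape != (6, 2):
        raise ValueError(f"expected exactly 6 (x, y) points, got shape {points.shape}")
    # collinearity check: rank of centered points
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(points).max())) < 2:
        raise ValueError("clicked points are collinear; cannot fit an ellipse")
    model = EllipseModel.from_estimate(points)
    if not model:
        raise ValueError("ellipse fit failed (degenerate point configuration)")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if a < b:  # enforce a = semi-major
        a, b = b, a
        theta += np.pi / 2.0
    if not (np.isfinite(a) and np.isfinite(b)) or b <= 0:
        raise ValueError("degenerate ellipse fit")
    residuals = model.residuals(points)
    return OpticDisc(
        clicked_points=points,
        center=(float(xc), float(yc)),
        a=float(a),
        b=float(b),
        rotation_deg=float(np.degrees(theta) % 180.0),
        residual_rms=float(np.sqrt(np.mean(residuals**2))),
    )


def pixel_size(disc: OpticDisc) -> float:
    """µm per pixel from the 1800 µm optic-disc convention.

    The longest disc diameter is taken as twice the fitted semi-major axis
    (the fit smooths click error), so pixel size = 1800 / (2·a).
    """
    if disc.a <= 0:
        raise ValueError("semi-major axis must be positive")
    return OPTIC_DISC_DIAMETER_UM / (2.0 * disc.a)


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def binarize_cadrads(score: int) -> int:
    """Binary class under model 1: 0 for CAD-RADS ≤ 1, 1 for CAD-RADS ≥ 2."""
    if score not in range(6):
        raise ValueError(f"CAD-RADS score must be in 0..5, got {score}")
    return 0 if score <= 1 else 1


def assign_cat(subject: SubjectRecord) -> int:
    """Significant-CAD label (model 2).

    CAT = 1 for subjects scheduled for intervention, with a prior stent or
    CABG, or stratified to CAD-RADS ≥ 4; CAT = 0 otherwise.
    """
    return int(
        bool(subject.scheduled_intervention)
        or bool(subject.prior_stent)
        or bool(subject.prior_cabg)
        or subject.cadrads >= 4
    )
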