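"""Zonal geometry: core / rim / invasion partition of a slice, the random
analysis quadrant, and radial invasion distances.

Boundaries between zones are user-drawn polygons straightened to ellipses
with ImageJ "Fit Ellipse" semantics (same area, centroid and second-order
central moments as the polygon interior), or estimated automatically from
the radial intensity profile when no polygons are supplied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .calibration import PixelCalibration
from .image_io import BoundaryPolygon
from .segmentation import NucleusRecord

logger = logging.getLogger("spheroidquant")

ZONE_CODES = {"outside": 0, "core": 1, "rim": 2, "invasion": 3}


class GeometryError(ValueError):
    pass


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Ellipse:
    """center (row, col) px; semi axes px; orientation = angle (radians,
    CCW) of the major axis from the column (+x) axis."""

    center: tuple
    semi_major: float
    semi_minor: float
    orientation: float

    @property
    def area(self) -> float:
        return math.pi * self.semi_major * self.semi_minor

    def implicit(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Quadratic form value; <= 1 inside the ellipse."""
        dy = np.asarray(rows, dtype=float) - self.center[0]
        dx = np.asarray(cols, dtype=float) - self.center[1]
        ct, st = math.cos(self.orientation), math.sin(self.orientation)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        return (u / self.semi_major) ** 2 + (v / self.semi_minor) ** 2

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.implicit(rows, cols) <= 1.0


def _polygon_moments(verts: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Exact area, centroid and second central moments of a polygon interior.

    Green's-theorem formulas in (x=col, y=row); returns
    (A, cx, cy, mu_xx, mu_yy, mu_xy) with mu per unit area (covariance).
    """
    y = verts[:, 0]
    x = verts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    A = cross.sum() / 2.0
    if abs(A) < 1e-12:
        raise GeometryError("degenerate (zero-area) polygon")
    cx = ((x + x1) * cross).sum() / (6.0 * A)
    cy = ((y + y1) * cross).sum() / (6.0 * A)
    Ixx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0  # ∫x²dA
    Iyy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0  # ∫y²dA
    Ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    mu_xx = Ixx / A - cx * cx
    mu_yy = Iyy / A - cy * cy
    mu_xy = Ixy / A - cx * cy
    return abs(A), cx, cy, mu_xx, mu_yy, mu_xy


def fit_boundary_ellipse(polygon: BoundaryPolygon | np.ndarray) -> Ellipse:
    """Straighten a polygon outline to its moment-equivalent ellipse.

    ImageJ Fit Ellipse semantics: the returned ellipse has the polygon
    interior's centroid and second-moment orientation/axis ratio, with
    both axes scaled so the areas agree exactly.
    """
    verts = polygon.vertices if isinstance(polygon, BoundaryPolygon) \
        else np.atleast_2d(np.asarray(polygon, dtype=float))
    A, cx, cy, mu_xx, mu_yy, mu_xy = _polygon_moments(verts)
    cov = np.array([[mu_xx, mu_xy], [mu_xy, mu_yy]])
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        raise GeometryError("degenerate polygon: zero second moment")
    # eigh sorts ascending: index 1 is the major axis
    a0 = 2.0 * math.sqrt(evals[1])
    b0 = 2.0 * math.sqrt(evals[0])
    scale = math.sqrt(A / (math.pi * a0 * b0))
    vx, vy = evecs[0, 1], evecs[1, 1]  # (x, y) components of major axis
    theta = math.atan2(vy, vx)
    if theta < -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    return Ellipse(center=(cy, cx), semi_major=a0 * scale,
                   semi_minor=b0 * scale, orientation=theta)


@dataclass
class ZoneMap:
    """Per-pixel zone partition of one slice.

    ``labels`` uses :data:`ZONE_CODES`; the spheroid centroid is the
    center of the core_rim ellipse.
    """

    labels: np.ndarray  # uint8, codes from ZONE_CODES
    centroid: tuple     # (row, col) px
    core_rim: Ellipse
    rim_invasion: Ellipse

    def zone_at(self, row: float, col: float) -> str:
        r, c = int(round(row)), int(round(col))
        h, w = self.labels.shape
        if not (0 <= r < h and 0 <= c < w):
            return "outside"
        code = int(self.labels[r, c])
        return {v: k for k, v in ZONE_CODES.items()}[code]

    def pixel_counts(self) -> dict:
        return {name: int((self.labels == code).sum())
                for name, code in ZONE_CODES.items()}


def build_zone_map(core_rim: Ellipse, rim_invasion: Ellipse,
                   image_shape: tuple) -> ZoneMap:
    """Partition a slice: inside core_rim → core; between the boundaries →
    rim; outside rim_invasion → invasion. Raises when the core_rim
    boundary is not contained in the rim_invasion boundary."""
    _check_containment(core_rim, rim_invasion)
    h, w = image_shape[-2], image_shape[-1]
    rows, cols = np.mgrid[0:h, 0:w]
    in_core = core_rim.contains(rows, cols)
    in_rim_outer = rim_invasion.contains(rows, cols)
    labels = np.full((h, w), ZONE_CODES["invasion"], dtype=np.uint8)
    labels[in_rim_outer] = ZONE_CODES["rim"]
    labels[in_core] = ZONE_CODES["core"]
    if not (in_rim_outer & ~in_core).any():
        logger.warning("build_zone_map: rim has 0 pixels (identical boundaries)")
    return ZoneMap(labels=labels, centroid=core_rim.center,
                   core_rim=core_rim, rim_invasion=rim_invasion)


def _check_containment(inner: Ellipse, outer: Ellipse, n_samples: int = 360) -> None:
    t = np.linspace(0, 2 * np.pi, n_samples, endpoint=False)
    ct, st = math.cos(inner.orientation), math.sin(inner.orientation)
    u = inner.semi_major * np.cos(t)
    v = inner.semi_minor * np.sin(t)
    cols = inner.center[1] + u * ct - v * st
    rows = inner.center[0] + u * st + v * ct
    outside = outer.implicit(rows, cols) > 1.0 + 1e-9
    if outside.any():
        frac = outside.mean()
        raise GeometryError(
            f"core_rim boundary lies outside rim_invasion boundary for "
            f"{frac:.0%} of its perimeter")


# ---------------------------------------------------------------------------
# automatic boundary estimation
# ---------------------------------------------------------------------------

def estimate_boundaries(stack, central_slice: int, *, smooth_sigma_px: float = 3.0,
                        ) -> tuple[BoundaryPolygon, BoundaryPolygon]:
    """Estimate circular core_rim / rim_invasion boundaries from the radial
    mean-intensity profile of the central slice.

    The rim_invasion radius is the outermost half-maximum crossing of the
    falling outer edge of the dense region; the core_rim radius is the
    inner edge of the densest ring (inward half-rise toward the ring
    peak). Intended as a convenience only — user-drawn polygons always
    take precedence.
    """
    from scipy.ndimage import gaussian_filter, gaussian_filter1d

    img = gaussian_filter(np.asarray(stack.voxels[central_slice], dtype=float),
                          smooth_sigma_px)
    h, w = img.shape
    total = img.sum()
    if total <= 0:
        raise EstimationError("empty slice; provide manual ROIs")
    rows, cols = np.mgrid[0:h, 0:w]
    cr = (rows * img).sum() / total
    cc = (cols * img).sum() / total
    r = np.hypot(rows - cr, cols - cc)
    rbin = r.astype(int)
    nmax = rbin.max() + 1
    sums = np.bincount(rbin.ravel(), weights=img.ravel(), minlength=nmax)
    counts = np.bincount(rbin.ravel(), minlength=nmax)
    profile = sums / np.maximum(counts, 1)
    profile = gaussian_filter1d(profile, 2.0)

    rmax_usable = int(min(cr, cc, h - 1 - cr, w - 1 - cc))
    profile = profile[:rmax_usable]
    if len(profile) < 10:
        raise EstimationError("no radial structure detected; provide manual ROIs")
    background = np.percentile(profile, 5)
    peak_r = int(np.argmax(profile))
    peak = profile[peak_r]
    if peak < background + 1e-6 or peak < 1.2 * background:
        raise EstimationError("no radial structure detected; provide manual ROIs")
    half = background + 0.5 * (peak - background)

    # outer boundary: outermost falling crossing of the half level
    above = profile >= half
    crossings = np.where(above[:-1] & ~above[1:])[0]
    if len(crossings) == 0:
        raise EstimationError("no outer intensity drop detected; provide manual ROIs")
    rim_invasion_r = float(crossings[-1]) + 1.0

    # inner boundary: walking inward from the ring peak, where the profile
    # first falls to the half level between core plateau and ring peak
    inner_region = profile[:peak_r + 1]
    core_level = np.median(inner_region[: max(peak_r // 2, 1)])
    half_in = core_level + 0.5 * (peak - core_level)
    below = np.where(inner_region < half_in)[0]
    core_rim_r = float(below[-1]) if len(below) else max(peak_r - 1.0, 1.0)

    def circle(radius: float, label: str) -> BoundaryPolygon:
        t = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        verts = np.column_stack([cr + radius * np.sin(t),
                                 cc + radius * np.cos(t)])
        return BoundaryPolygon(verts, label)

    return circle(core_rim_r, "core_rim"), circle(rim_invasion_r, "rim_invasion")


# ---------------------------------------------------------------------------
# quadrant + radial measures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadrantSelection:
    """One of the 4 axis-aligned quadrants anchored at the spheroid centroid.

    Index convention on (drow, dcol) = (row - centroid_row, col -
    centroid_col): 0 → (+,+); 1 → (+,−); 2 → (−,−); 3 → (−,+); pixels on
    the centroid axes (zero offset) belong to no quadrant.
    """

    index: int
    centroid: tuple
    seed: int

    def mask(self, image_shape: tuple) -> np.ndarray:
        h, w = image_shape[-2], image_shape[-1]
        rows, cols = np.mgrid[0:h, 0:w]
        return self.contains(rows, cols)

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        drow = np.asarray(rows, dtype=float) - self.centroid[0]
        dcol = np.asarray(cols, dtype=float) - self.centroid[1]
        signs = [(1, 1), (1, -1), (-1, -1), (-1, 1)][self.index]
        return (np.sign(drow) == signs[0]) & (np.sign(dcol) == signs[1])


def select_quadrant(zone_map: ZoneMap, seed: int) -> QuadrantSelection:
    """Uniform seeded draw of the analysis quadrant."""
    rng = np.random.default_rng(seed)
    return QuadrantSelection(index=int(rng.integers(4)),
                             centroid=zone_map.centroid, seed=seed)


def radial_distance(record: NucleusRecord, centroid: tuple,
                    calibration: PixelCalibration) -> float:
    """In-plane Euclidean distance (µm) from the spheroid centroid; the
    estimate of the distance the cell has migrated. Stored on the record."""
    d_px = math.hypot(record.centroid[0] - centroid[0],
                      record.centroid[1] - centroid[1])
    record.radial_distance_um = calibration.length_um(d_px)
    return record.radial_distance_um


def assign_zones(records: list[NucleusRecord], zone_map: ZoneMap,
                 quadrant: QuadrantSelection | None = None, *,
                 restrict_invasion_to_quadrant: bool = False,
                 calibration: PixelCalibration | None = None,
                 ) -> list[NucleusRecord]:
    """Set each record's zone from the zone label at its centroid pixel.

    With ``restrict_invasion_to_quadrant``, invasion-zone records outside
    the selected quadrant become ``unassigned`` (excluded from counts);
    core and rim counts always use the full regions. Also fills the radial
    distance when a calibration is given.
    """
    for rec in records:
        zone = zone_map.zone_at(*rec.centroid)
        if zone == "outside":
            logger.warning("record %d centroid outside image; marked unassigned",
                           rec.id)
            rec.zone = "unassigned"
            continue
        if (restrict_invasion_to_quadrant and quadrant is not None
                and zone == "invasion"
                and not bool(quadrant.contains(rec.centroid[0], rec.centroid[1]))):
            rec.zone = "unassigned"
        else:
            rec.zone = zone
        if calibration is not None:
            radial_distance(rec, zone_map.centroid, calibration)
    return records
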