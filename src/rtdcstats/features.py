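"""Per-cell morphological and texture parameters from a contour.

In real-time deformability cytometry (RT-DC) every imaged cell yields a
closed pixel-coordinate contour and, optionally, a bright-field grayscale
patch.  All morphometric descriptors used downstream — projected area,
solid-of-revolution volume, bounding box, circularity/deformation on the
convex hull, second-moment inertia ratio and orientation, area ratio,
symmetry ratios, brightness statistics and the 13 Haralick texture
features — are computed here from those two inputs alone.

Coordinate convention: pixel coordinates with the origin at the top left,
``x`` along the flow direction, ``y`` downward; contour vertices sit on
pixel centers.  Areas come from the shoelace formula on vertex
coordinates (no half-pixel dilation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, box
from skimage.measure import grid_points_in_poly

__all__ = [
    "Contour",
    "ImagePatch",
    "FeatureRecord",
    "HARALICK_NAMES",
    "compute_area",
    "compute_bounding_box",
    "compute_deformation",
    "compute_volume",
    "compute_inertia_ratio",
    "compute_orientation",
    "compute_area_ratio",
    "compute_symmetry",
    "compute_brightness",
    "compute_haralick",
    "equivalent_diameter",
    "extract_features",
]


class DegenerateContourError(ValueError):
    """Raised when a contour encloses (numerically) zero area."""


@dataclass(frozen=True)
class Contour:
    """Closed polygon of one cell in pixel coordinates.

    Parameters
    ----------
    points : (n, 2) array
        Ordered ``(x, y)`` vertices; the last vertex implicitly connects
        back to the first.  At least 3 points, all finite.
    pixel_size : float
        Physical size of one pixel in μm (isotropic).
    """

    points: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("contour needs an (n>=3, 2) point array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("contour coordinates must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "points", pts)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def polygon(self) -> Polygon:
        return Polygon(self.points)

    def centroid(self) -> np.ndarray:
        """Area centroid of the enclosed polygon, in pixel coordinates."""
        c = self.polygon().centroid
        return np.array([c.x, c.y])


@dataclass(frozen=True)
class ImagePatch:
    """Grayscale patch covering a contour's bounding box.

    ``values[row, col]`` maps to pixel-center coordinates
    ``(x, y) = (origin[0] + col, origin[1] + row)``.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    bit_depth: int = 8

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("image patch must be 2-D")
        if v.min() < 0 or v.max() >= 2 ** self.bit_depth:
            raise ValueError("grayscale values exceed declared bit depth")
        object.__setattr__(self, "values", v)


#: Fixed output order of :func:`compute_haralick`.
HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)


@dataclass
class FeatureRecord:
    """All per-event descriptors, in physical units (μm-based)."""

    A: float
    V: float
    Lx: float
    Ly: float
    C: float
    D: float
    I: float
    phi: float
    Delta: float
    Sx: float
    Sy: float
    d_eq: float
    B: float = np.nan
    BStD: float = np.nan
    haralick: np.ndarray = field(default_factory=lambda: np.full(13, np.nan))
    E: float = np.nan

    def as_dict(self) -> dict[str, float]:
        d = {
            k: getattr(self, k)
            for k in ("A", "V", "Lx", "Ly", "C", "D", "I", "phi",
                      "Delta", "Sx", "Sy", "d_eq", "B", "BStD", "E")
        }
        for name, val in zip(HARALICK_NAMES, self.haralick):
            d[f"h_{name}"] = val
        return d


def _valid_polygon(contour: Contour) -> Polygon:
    poly = contour.polygon()
    if poly.area <= 0 or not poly.is_valid:
        # fall back: a self-touching polygon can still report a usable area
        if poly.area <= 0:
            raise DegenerateContourError("contour encloses zero area")
    return poly


def compute_area(contour: Contour) -> float:
    """Projected cell area in μm² (shoelace on the raw contour)."""
    poly = _valid_polygon(contour)
    return poly.area * contour.pixel_size ** 2


def compute_bounding_box(contour: Contour) -> tuple[float, float]:
    """Axis-aligned extents (Lx along flow, Ly across) in μm."""
    pts = contour.points
    ext = pts.max(axis=0) - pts.min(axis=0)
    return ext[0] * contour.pixel_size, ext[1] * contour.pixel_size


def compute_deformation(contour: Contour) -> tuple[float, float, Contour]:
    """Circularity C, deformation D = 1 − C, and the convex hull.

    The perimeter enters through the convex hull so that corrugated,
    non-convex contours do not inflate the deformation; the area is the
    raw contour area.  ``C = 2·sqrt(πA)/l`` equals 1 for a circle.
    """
    poly = _valid_polygon(contour)
    hull = poly.convex_hull
    perimeter = hull.length
    circ = 2.0 * math.sqrt(math.pi * poly.area) / perimeter
    hull_pts = np.asarray(hull.exterior.coords)[:-1]
    return circ, 1.0 - circ, Contour(hull_pts, contour.pixel_size)


def _revolution_volume(points: np.ndarray) -> float:
    """|π ∮ y² dx| along a closed polygon boundary (pixel units³)."""
    x = points[:, 0]
    y = points[:, 1]
    x2 = np.roll(x, -1)
    y2 = np.roll(y, -1)
    integral = np.sum((x2 - x) * (y * y + y * y2 + y2 * y2) / 3.0)
    return abs(math.pi * integral)


def compute_volume(contour: Contour) -> float:
    """Solid-of-revolution volume (μm³) about the flow axis through the centroid.

    The contour is a 2-D projection; assuming rotational symmetry about
    the axis z through the centroid along the flow direction, each half
    of the contour (below and above the axis) is revolved to give an
    independent volume estimate, and the two are averaged.  The per-half
    estimate is the exact piecewise-linear integral π∮y²dx.
    """
    poly = _valid_polygon(contour)
    cx, cy = poly.centroid.x, poly.centroid.y
    pts = contour.points - [cx, cy]
    shifted = Polygon(pts).buffer(0)  # heal minor self-touches
    span = np.abs(pts).max() * 4 + 1
    halves = []
    for clip in (box(-span, -span, span, 0.0), box(-span, 0.0, span, span)):
        piece = shifted.intersection(clip)
        if piece.is_empty or piece.area <= 0:
            continue
        vol = 0.0
        geoms = getattr(piece, "geoms", [piece])
        for g in geoms:
            vol += _revolution_volume(np.asarray(g.exterior.coords)[:-1])
        halves.append(vol)
    if not halves:
        raise DegenerateContourError("contour degenerate about the flow axis")
    if len(halves) == 1:
        warnings.warn("contour lies on one side of the flow axis; "
                      "single-sided volume estimate", stacklevel=2)
        return halves[0] * contour.pixel_size ** 3
    return 0.5 * (halves[0] + halves[1]) * contour.pixel_size ** 3


def _second_moments(contour: Contour) -> tuple[float, float, float]:
    """Centroidal second moments (Ixx=∬y², Iyy=∬x², P=∬xy) of the area.

    Closed-form polygon formulas; orientation-independent (absolute
    value through the signed area).  Pixel units⁴.
    """
    x = contour.x
    y = contour.y
    x2 = np.roll(x, -1)
    y2 = np.roll(y, -1)
    cross = x * y2 - x2 * y
    a_signed = 0.5 * np.sum(cross)
    if a_signed == 0:
        raise DegenerateContourError("zero-area contour")
    cx = np.sum((x + x2) * cross) / (6.0 * a_signed)
    cy = np.sum((y + y2) * cross) / (6.0 * a_signed)
    ixx = np.sum((y * y + y * y2 + y2 * y2) * cross) / 12.0
    iyy = np.sum((x * x + x * x2 + x2 * x2) * cross) / 12.0
    pxy = np.sum((x * y2 + 2 * x * y + 2 * x2 * y2 + x2 * y) * cross) / 24.0
    area = abs(a_signed)
    sign = math.copysign(1.0, a_signed)
    ixx = sign * ixx - area * cy * cy
    iyy = sign * iyy - area * cx * cx
    pxy = sign * pxy - area * cx * cy
    return ixx, iyy, pxy


def compute_inertia_ratio(contour: Contour) -> float:
    """Inertia ratio I = Iyy/Ixx of the enclosed area about the centroid.

    Measures elongation along the flow direction: 1 for a circle,
    (a/b)² for an x-aligned ellipse with semi-axes a, b.  Computed on
    the raw contour (robust against pixelation; no hull needed).
    """
    ixx, iyy, _ = _second_moments(contour)
    if ixx <= 0:
        raise DegenerateContourError("Ixx is zero; contour degenerate")
    return iyy / ixx


def compute_orientation(contour: Contour) -> float:
    """Angle φ between the coordinate axes and the principal axes, radians.

    Quadrant-aware: φ = ½·atan2(2·∬xy, Iyy − Ixx), mapped to
    (−π/2, π/2]; isotropic shapes (circle) return 0 by convention.
    """
    ixx, iyy, pxy = _second_moments(contour)
    scale = ixx + iyy
    if abs(2 * pxy) <= 1e-9 * scale and abs(iyy - ixx) <= 1e-9 * scale:
        return 0.0  # isotropic: principal axes undefined
    phi = 0.5 * math.atan2(2.0 * pxy, iyy - ixx)
    if phi <= -math.pi / 2:
        phi += math.pi
    elif phi > math.pi / 2:
        phi -= math.pi
    return phi


def compute_area_ratio(contour: Contour) -> float:
    """Δ = A_hull / A_contour ≥ 1; equals 1 for convex contours.

    The modulus-validity gate keeps only 1.0 ≤ Δ ≤ 1.05 (smooth, convex
    shapes for which linear-elastic modulus extraction is meaningful).
    """
    poly = _valid_polygon(contour)
    return poly.convex_hull.area / poly.area


def compute_symmetry(contour: Contour) -> tuple[float, float]:
    """Symmetry ratios (Sx, Sy) about the centroid axes.

    The contour is split by the flow axis through the centroid into
    upper/lower parts of area A_up, A_low, giving
    Sx = (A_up − A_low)/(A_up + A_low); Sy uses the orthogonal axis.
    Both lie in [−1, 1] and vanish for mirror-symmetric shapes.
    """
    poly = _valid_polygon(contour).buffer(0)
    cx, cy = poly.centroid.x, poly.centroid.y
    b = poly.bounds
    pad = max(b[2] - b[0], b[3] - b[1]) + 1.0
    out = []
    for upper, lower in (
        (box(b[0] - pad, b[1] - pad, b[2] + pad, cy),
         box(b[0] - pad, cy, b[2] + pad, b[3] + pad)),
        (box(b[0] - pad, b[1] - pad, cx, b[3] + pad),
         box(cx, b[1] - pad, b[2] + pad, b[3] + pad)),
    ):
        a_up = poly.intersection(upper).area
        a_low = poly.intersection(lower).area
        if a_up + a_low <= 0:
            raise DegenerateContourError("clipping produced empty halves")
        out.append((a_up - a_low) / (a_up + a_low))
    return out[0], out[1]


def _mask_for(image: ImagePatch, contour: Contour) -> np.ndarray:
    """Boolean mask of image pixels whose centers lie inside the contour."""
    rows, cols = image.values.shape
    # grid_points_in_poly evaluates integer grid points (r, c); shift the
    # contour into the patch frame with (row, col) = (y - oy, x - ox).
    verts = np.column_stack([
        contour.y - image.origin[1],
        contour.x - image.origin[0],
    ])
    return grid_points_in_poly((rows, cols), verts)


def compute_brightness(image: ImagePatch, contour: Contour) -> tuple[float, float]:
    """Mean and standard deviation of grayscale values inside the contour."""
    mask = _mask_for(image, contour)
    if not mask.any():
        raise ValueError("no pixel centers inside the contour")
    vals = image.values[mask].astype(float)
    return float(vals.mean()), float(vals.std())


def _glcm(image: ImagePatch, mask: np.ndarray, levels: int) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix of in-mask neighbor pairs.

    Gray values are re-binned to ``levels`` equal-width bins over the full
    declared bit depth; the four unique distance-1 offsets (E, S, SE, NE)
    are accumulated, each pair counted in both directions; only pairs with
    both pixels inside the mask contribute.
    """
    binned = (image.values.astype(np.int64) * levels) >> image.bit_depth
    binned = np.clip(binned, 0, levels - 1)
    counts = np.zeros((levels, levels), dtype=np.int64)
    offsets = ((0, 1), (1, 0), (1, 1), (1, -1))
    rows, cols = binned.shape
    for dr, dc in offsets:
        r0 = slice(max(0, -dr), rows - max(0, dr))
        c0 = slice(max(0, -dc), cols - max(0, dc))
        r1 = slice(max(0, dr), rows + min(0, dr))
        c1 = slice(max(0, dc), cols + min(0, dc))
        valid = mask[r0, c0] & mask[r1, c1]
        a = binned[r0, c0][valid]
        b = binned[r1, c1][valid]
        np.add.at(counts, (a, b), 1)
        np.add.at(counts, (b, a), 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("mask too small: no in-mask neighbor pairs")
    return counts / total


def haralick_from_glcm(p: np.ndarray) -> np.ndarray:
    """The 13 classical Haralick texture statistics of a normalized GLCM.

    Order per :data:`HARALICK_NAMES`: angular second moment, contrast,
    correlation, sum of squares (variance), inverse difference moment,
    sum average, sum variance, sum entropy, entropy, difference variance,
    difference entropy, and the two information measures of correlation.
    """
    lv = p.shape[0]
    i = np.arange(lv)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = np.sum(i * px)
    mu_y = np.sum(i * py)
    var_x = np.sum((i - mu_x) ** 2 * px)
    var_y = np.sum((i - mu_y) ** 2 * py)

    # p_{x+y}(k), k = 0..2(lv-1), and p_{x-y}(k), k = 0..lv-1
    p_sum = np.zeros(2 * lv - 1)
    np.add.at(p_sum, (ii + jj).ravel(), p.ravel())
    p_diff = np.zeros(lv)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())

    def entropy(q):
        q = q[q > 0]
        return -np.sum(q * np.log(q))

    asm = np.sum(p * p)
    contrast = np.sum((ii - jj) ** 2 * p)
    if var_x > 0 and var_y > 0:
        correlation = (np.sum(ii * jj * p) - mu_x * mu_y) / math.sqrt(var_x * var_y)
    else:
        correlation = 0.0
    variance = np.sum((ii - (mu_x + mu_y) / 2.0) ** 2 * p)
    idm = np.sum(p / (1.0 + (ii - jj) ** 2))
    k_sum = np.arange(2 * lv - 1)
    sum_average = np.sum(k_sum * p_sum)
    sum_entropy = entropy(p_sum)
    sum_variance = np.sum((k_sum - sum_average) ** 2 * p_sum)
    ent = entropy(p)
    k_diff = np.arange(lv)
    diff_average = np.sum(k_diff * p_diff)
    difference_variance = np.sum((k_diff - diff_average) ** 2 * p_diff)
    difference_entropy = entropy(p_diff)

    hx = entropy(px)
    hy = entropy(py)
    pxpy = np.outer(px, py)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = -np.sum(p[nz] * np.log(pxpy[nz]))
    hxy2 = entropy(pxpy.ravel())
    denom = max(hx, hy)
    imc1 = (ent - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - math.exp(-2.0 * (hxy2 - ent))
    imc2 = math.sqrt(max(arg, 0.0))

    return np.array([
        asm, contrast, correlation, variance, idm, sum_average,
        sum_variance, sum_entropy, ent, difference_variance,
        difference_entropy, imc1, imc2,
    ])


def compute_haralick(image: ImagePatch, contour: Contour,
                     levels: int = 16) -> np.ndarray:
    """13 Haralick features of the texture inside the contour.

    Built on a symmetric normalized gray-level co-occurrence matrix of
    distance-1 pixel pairs with both pixels inside the contour; gray
    values re-binned to ``levels`` (default 16) equal-width bins.
    """
    mask = _mask_for(image, contour)
    p = _glcm(image, mask, levels)
    return haralick_from_glcm(p)


def equivalent_diameter(area: float) -> float:
    """Diameter d = 2·sqrt(A/π) of a circle with the given area (μm)."""
    if area <= 0:
        raise ValueError("area must be positive")
    return 2.0 * math.sqrt(area / math.pi)


def extract_features(contour: Contour, image: ImagePatch | None = None,
                     levels: int = 16) -> FeatureRecord:
    """Compute the full per-event feature record from one contour."""
    a = compute_area(contour)
    circ, deform, _ = compute_deformation(contour)
    lx, ly = compute_bounding_box(contour)
    sx, sy = compute_symmetry(contour)
    rec = FeatureRecord(
        A=a,
        V=compute_volume(contour),
        Lx=lx,
        Ly=ly,
        C=circ,
        D=deform,
        I=compute_inertia_ratio(contour),
        phi=compute_orientation(contour),
        Delta=compute_area_ratio(contour),
        Sx=sx,
        Sy=sy,
        d_eq=equivalent_diameter(a),
    )
    if image is not None:
        rec.B, rec.BStD = compute_brightness(image, contour)
        rec.haralick = compute_haralick(image, contour, levels=levels)
    return rec
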