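"""Closed-outline processing and shape analysis for fossil insect wings.

Implements the outline pipeline used throughout the package: arc-length
resampling of digitized wing outlines, elliptical Fourier descriptors (EFD)
with first-harmonic normalization, harmonic power spectra, PCA of the
normalized coefficients (shape space), area proportions of labeled wing
regions (costal area, clavus, extended costal area), and construction of
the combined forewing + hind-wing silhouette.

Coordinates are planar, in mm.  Outlines are stored counterclockwise with
implicit closure (last point is not a repeat of the first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely import affinity
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

logger = logging.getLogger("palaeoflight")


class ParameterError(ValueError):
    """A numeric argument is outside its valid domain."""


class GeometryError(ValueError):
    """An outline violates a geometric precondition (e.g. self-intersects)."""


# ---------------------------------------------------------------------------
# Outline container
# ---------------------------------------------------------------------------

REGION_NAMES = ("costal", "clavus", "peco")


@dataclass
class WingOutline:
    """A closed, simple, counterclockwise planar outline of a single wing.

    Parameters
    ----------
    points : (K, 2) array
        Ordered boundary vertices in mm; closure is implicit.  Clockwise
        input is silently reversed (and logged).
    wing : str
        ``"forewing"``, ``"hindwing"`` or ``"combined"``.
    regions : dict
        Optional labeled sub-polygons (``costal``, ``clavus``, ``peco``),
        each a (M, 2) vertex array contained in the outline.
    multi_part : bool
        Set by :func:`combine_wings` when the union is disconnected.
    parts : list
        Extra polygon parts when ``multi_part`` is true.
    """

    points: np.ndarray
    wing: str = "forewing"
    regions: dict = field(default_factory=dict)
    multi_part: bool = False
    parts: list = field(default_factory=list)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise GeometryError("outline needs at least 3 planar points")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("outline contains non-finite coordinates")
        if signed_area(pts) < 0:
            logger.debug("clockwise outline reversed to counterclockwise")
            pts = pts[::-1].copy()
        self.points = pts

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    @property
    def area(self) -> float:
        return signed_area(self.points)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def is_simple(self) -> bool:
        return bool(Polygon(self.points).is_valid)

    def validate_simple(self):
        if not self.is_simple():
            raise GeometryError("outline is self-intersecting")


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area (positive for counterclockwise orientation)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon (shoelace formula)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def resample_outline(points: np.ndarray, n_points: int,
                     canonical_start: bool = True) -> np.ndarray:
    """Resample a closed polyline to ``n_points`` equally spaced (arc length).

    With ``canonical_start`` the traversal starts at the vertex farthest from
    the polygon centroid, which makes the output independent of where the
    digitized point sequence happened to begin.
    """
    pts = np.asarray(points, dtype=float)
    if n_points < 3:
        raise ParameterError("n_points must be >= 3")
    if canonical_start:
        c = polygon_centroid(pts)
        start = int(np.argmax(np.hypot(*(pts - c).T)))
        pts = np.roll(pts, -start, axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    t = np.concatenate([[0.0], np.cumsum(seglen)])
    total = t[-1]
    if total <= 0:
        raise GeometryError("degenerate outline with zero perimeter")
    s = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(s, t, closed[:, 0])
    y = np.interp(s, t, closed[:, 1])
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# Elliptical Fourier descriptors
# ---------------------------------------------------------------------------


@dataclass
class HarmonicSeries:
    """Elliptical Fourier coefficients of a closed outline.

    ``coeffs`` has shape (N, 4) with columns (a_n, b_n, c_n, d_n) for the
    x- and y-series.  ``offset`` is the (A0, C0) locus term.
    """

    coeffs: np.ndarray
    offset: tuple = (0.0, 0.0)
    normalized: bool = False

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[0]


def _efd_coefficients(points: np.ndarray, n_harmonics: int):
    """Exact EFD integrals of the piecewise-linear closed contour.

    Follows Kuhl & Giardina's closed-form segment sums, which are exact for
    a polygonal contour (no quadrature error).
    """
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    d = np.diff(closed, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    if np.any(dt <= 0):
        keep = dt > 0
        d, dt = d[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T

    n = np.arange(1, n_harmonics + 1)[:, None]           # (N,1)
    const = T / (2.0 * n[:, 0] ** 2 * np.pi ** 2)        # (N,)
    cosp, sinp = np.cos(n * phi), np.sin(n * phi)        # (N,K+1)
    dcos = cosp[:, 1:] - cosp[:, :-1]
    dsin = sinp[:, 1:] - sinp[:, :-1]
    fx, fy = d[:, 0] / dt, d[:, 1] / dt
    a = const * (dcos @ fx)
    b = const * (dsin @ fx)
    c = const * (dcos @ fy)
    dd = const * (dsin @ fy)

    # locus (A0, C0)
    xi = np.cumsum(d[:, 0]) - d[:, 0] - fx * t[:-1]
    delta = np.cumsum(d[:, 1]) - d[:, 1] - fy * t[:-1]
    dt2 = t[1:] ** 2 - t[:-1] ** 2
    A0 = closed[0, 0] + (1.0 / T) * np.sum(fx * dt2 / 2.0 + xi * dt)
    C0 = closed[0, 1] + (1.0 / T) * np.sum(fy * dt2 / 2.0 + delta * dt)
    return np.column_stack([a, b, c, dd]), (float(A0), float(C0))


def _phase_rotate(coeffs: np.ndarray, theta: float) -> np.ndarray:
    """Shift the curve's starting phase: C_n -> C_n @ R(n*theta)."""
    out = np.empty_like(coeffs)
    for i in range(coeffs.shape[0]):
        n = i + 1
        ct, st = np.cos(n * theta), np.sin(n * theta)
        rot = np.array([[ct, -st], [st, ct]])
        out[i] = (coeffs[i].reshape(2, 2) @ rot).ravel()
    return out


def _normalize_coeffs(coeffs: np.ndarray) -> np.ndarray:
    """First-harmonic normalization (size, rotation, starting point).

    The residual 180-degree phase ambiguity is resolved by a deterministic
    sign canonicalization of the higher harmonics, so that any rigid
    rotation, uniform scaling or starting-point shift of the input maps to
    the same normalized coefficients.
    """
    a1, b1, c1, d1 = coeffs[0]
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1),
                             a1 ** 2 + c1 ** 2 - b1 ** 2 - d1 ** 2)
    out = _phase_rotate(coeffs, theta)
    psi = np.arctan2(out[0, 2], out[0, 0])
    rot = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    for i in range(out.shape[0]):
        out[i] = (rot @ out[i].reshape(2, 2)).ravel()
    scale = abs(out[0, 0])
    if scale <= 0:
        raise GeometryError("degenerate first harmonic; cannot normalize")
    out = out / scale
    # theta is only defined modulo pi; the alternative branch multiplies
    # harmonic n by (-1)^(n+1).  Pick the branch whose first non-negligible
    # higher-harmonic entry is positive.
    if out.shape[0] > 1:
        flip = out.copy()
        for i in range(1, flip.shape[0]):
            flip[i] *= (-1.0) ** (i + 2)          # (-1)^(n+1), n = i+1
        flat, flipflat = out[1:].ravel(), flip[1:].ravel()
        idx = np.nonzero(np.abs(flat) > 1e-9)[0]
        if idx.size and flat[idx[0]] < 0 and flipflat[idx[0]] > 0:
            out = flip
    return out


def efd_forward(outline: WingOutline, n_harmonics: int = 7,
                n_points: int = 300, normalize: bool = True) -> HarmonicSeries:
    """Elliptical Fourier transform of a wing outline.

    The outline is resampled to ``n_points`` equally spaced boundary points
    (starting from a canonical anchor) and the exact EFD integrals of the
    resampled polygon are taken.  With ``normalize``, coefficients are made
    invariant to size, rotation and starting point via the first harmonic.
    """
    if n_harmonics < 1:
        raise ParameterError("n_harmonics must be >= 1")
    if n_points < 4 * n_harmonics:
        raise ParameterError(
            f"n_points={n_points} insufficient for {n_harmonics} harmonics "
            f"(need >= {4 * n_harmonics}); increase n_points")
    outline.validate_simple()
    pts = resample_outline(outline.points, n_points)
    coeffs, offset = _efd_coefficients(pts, n_harmonics)
    if normalize:
        coeffs = _normalize_coeffs(coeffs)
        offset = (0.0, 0.0)
    return HarmonicSeries(coeffs=coeffs, offset=offset, normalized=normalize)


def efd_inverse(h: HarmonicSeries, n_points: int = 300) -> WingOutline:
    """Reconstruct a closed outline from its Fourier coefficients."""
    if h.n_harmonics < 1:
        raise ParameterError("need at least one harmonic")
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, h.n_harmonics + 1)[:, None]
    ang = 2.0 * np.pi * n * t[None, :]
    cosa, sina = np.cos(ang), np.sin(ang)
    a, b, c, d = h.coeffs.T
    x = h.offset[0] + a @ cosa + b @ sina
    y = h.offset[1] + c @ cosa + d @ sina
    return WingOutline(np.column_stack([x, y]), wing="forewing")


def harmonic_power(h: HarmonicSeries) -> np.ndarray:
    """Cumulative harmonic power fractions.

    Per-harmonic power is (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2; the returned
    vector is the running sum divided by the total, so it is nondecreasing
    and ends at 1.
    """
    power = 0.5 * np.sum(h.coeffs ** 2, axis=1)
    total = power.sum()
    if total <= 0:
        raise ParameterError("all-zero harmonic series has undefined power")
    return np.cumsum(power) / total


# ---------------------------------------------------------------------------
# Shape PCA
# ---------------------------------------------------------------------------


@dataclass
class ShapeSpace:
    """PCA of flattened normalized EFD coefficient vectors."""

    scores: np.ndarray           # (n_taxa, k)
    loadings: np.ndarray         # (n_features, k)
    variance_ratio: np.ndarray   # (k,)
    dropped_normalized: bool = True


def shape_pca(series: list, drop_normalized: bool = True) -> ShapeSpace:
    """Centered PCA of per-taxon harmonic coefficients.

    With ``drop_normalized`` the three coefficients fixed by first-harmonic
    normalization (a1 = 1, b1 = 0, c1 = 0) are excluded from the feature
    vector, as is common EFD-PCA practice.
    """
    if len(series) < 3:
        raise ParameterError("shape PCA needs at least 3 taxa")
    n_h = {s.n_harmonics for s in series}
    if len(n_h) != 1:
        raise ParameterError("all taxa must share the same harmonic count")
    X = np.array([s.coeffs.ravel() for s in series])
    if drop_normalized:
        X = np.delete(X, [0, 1, 2], axis=1)   # a1, b1, c1
    mean = X.mean(axis=0)
    Xc = X - mean
    u, sv, vt = np.linalg.svd(Xc, full_matrices=False)
    total = np.sum(sv ** 2)
    if total <= 1e-30:
        k = sv.size
        return ShapeSpace(np.zeros((X.shape[0], k)), vt.T,
                          np.zeros(k), drop_normalized)
    scores = u * sv
    ratio = sv ** 2 / total
    return ShapeSpace(scores, vt.T, ratio, drop_normalized)


# ---------------------------------------------------------------------------
# Region area proportions
# ---------------------------------------------------------------------------


def region_area_proportions(outline: WingOutline) -> dict:
    """Area proportions of labeled forewing regions.

    Returns a dict with keys ``S_costal``, ``S_clavus`` and ``Peco`` for
    whichever of the ``costal``, ``clavus`` and ``peco`` sub-polygons are
    present on the outline; absent regions are simply absent from the
    result (not reported as zero).  Each value is shoelace area of the
    sub-polygon divided by shoelace area of the whole forewing.
    """
    whole = abs(signed_area(outline.points))
    if whole <= 0:
        raise GeometryError("outline has zero area")
    keymap = {"costal": "S_costal", "clavus": "S_clavus", "peco": "Peco"}
    out = {}
    for name, key in keymap.items():
        if name in outline.regions:
            out[key] = abs(signed_area(outline.regions[name])) / whole
    return out


# ---------------------------------------------------------------------------
# Combined wing outline
# ---------------------------------------------------------------------------


def _poly_to_points(poly: Polygon) -> np.ndarray:
    pts = np.asarray(poly.exterior.coords)[:-1]
    if signed_area(pts) < 0:
        pts = pts[::-1]
    return pts


def combine_wings(forewing: WingOutline, hindwing: WingOutline,
                  rotation_deg: float = 0.0,
                  translation: tuple = (0.0, 0.0)) -> WingOutline:
    """Union silhouette of a coupled forewing and hind wing.

    The hind wing is rotated by ``rotation_deg`` about its centroid and then
    translated before the polygon union is taken.  If the placed polygons do
    not touch, the result carries ``multi_part=True`` (with the parts kept)
    and a warning is logged; the caller decides how to proceed.
    """
    forewing.validate_simple()
    hindwing.validate_simple()
    fw = Polygon(forewing.points)
    hw = Polygon(hindwing.points)
    if rotation_deg:
        hw = affinity.rotate(hw, rotation_deg, origin="centroid")
    hw = affinity.translate(hw, xoff=translation[0], yoff=translation[1])
    merged = unary_union([fw, hw])
    if isinstance(merged, MultiPolygon):
        logger.warning("combine_wings: placed wings are disjoint; "
                       "returning multi-part union")
        parts = sorted(merged.geoms, key=lambda g: g.area, reverse=True)
        main = _poly_to_points(parts[0])
        return WingOutline(main, wing="combined", multi_part=True,
                           parts=[_poly_to_points(p) for p in parts[1:]])
    return WingOutline(_poly_to_points(merged), wing="combined")


# ---------------------------------------------------------------------------
# TPS / CSV outline I/O
# ---------------------------------------------------------------------------


def write_tps(path, outlines: dict):
    """Write outlines to a TPS file using OUTLINES/POINTS records.

    ``outlines`` maps taxon id -> WingOutline (or (K,2) array).
    """
    with open(path, "w") as fh:
        for tid, out in outlines.items():
            pts = out.points if isinstance(out, WingOutline) else np.asarray(out)
            fh.write("OUTLINES=1\n")
            fh.write(f"POINTS={len(pts)}\n")
            for x, y in pts:
                fh.write(f"{x:.6f} {y:.6f}\n")
            fh.write(f"ID={tid}\n")


def read_tps(path) -> dict:
    """Read a TPS outline file written by :func:`write_tps` (or tpsDig)."""
    out, pts, tid, expected = {}, [], None, None
    pending = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            up = line.upper()
            if up.startswith("OUTLINES="):
                pts = []
            elif up.startswith("POINTS="):
                expected = int(line.split("=", 1)[1])
            elif up.startswith("ID="):
                tid = line.split("=", 1)[1]
                if expected is not None and len(pts) != expected:
                    raise GeometryError(
                        f"TPS record {tid}: expected {expected} points, "
                        f"got {len(pts)}")
                out[tid] = WingOutline(np.array(pts, dtype=float))
                pts, expected = [], None
            else:
                xy = line.split()
                if len(xy) == 2:
                    pts.append([float(xy[0]), float(xy[1])])
    if pts:
        pending.append(len(pts))
        raise GeometryError("TPS file ended inside an outline record")
    return out


def read_xy_csv(path) -> np.ndarray:
    """Read an outline from a two-column x,y CSV (header optional)."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParameterError("outline CSV needs two columns (x, y)")
    return df.iloc[:, :2].to_numpy(dtype=float)
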