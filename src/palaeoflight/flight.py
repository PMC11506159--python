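"""Flight-performance proxies from wing planform and body geometry.

The model chain: wing outlines give planform metrics (span *b*, area *S*,
mean chord *c* = S/b, aspect ratio *AR* = b^2/S); linear body dimensions give
modeled segment volumes (ellipsoidal pro- and mesothorax, conical abdomen);
assuming insect density equal to water (1 g/cm^3) the volumes become body and
flight-muscle masses; wing loading *WL* = m_body / S_total links the two.
Under steady weight support flight speed scales as sqrt(WL), and available
mass-specific flight power scales with the relative flight-muscle mass
m*_muscle = m_muscle / m_body, so cohort comparisons of WL, m*_muscle and AR
are comparisons of speed, power and efficiency.

Lengths are mm, areas mm^2 (cm^2 only where stated), volumes mm^3, masses g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from palaeoflight.wing_geometry import (
    GeometryError,
    ParameterError,
    WingOutline,
    signed_area,
)

MM3_TO_G = 1.0e-3      # 1 mm^3 of water weighs 1e-3 g
MM2_TO_CM2 = 1.0e-2


@dataclass
class BodyMeasurements:
    """Linear body dimensions in mm.

    ``l_pt`` and ``l_mt`` are prothoracic and mesothoracic lengths (their sum
    is the thorax length); ``w_thorax`` is thorax width; ``l_abdomen`` the
    abdominal length.
    """

    w_thorax: float
    l_pt: float
    l_mt: float
    l_abdomen: float
    group: str = ""

    def __post_init__(self):
        for name in ("w_thorax", "l_pt", "l_mt", "l_abdomen"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be positive and finite")

    @property
    def l_thorax(self) -> float:
        return self.l_pt + self.l_mt


@dataclass
class MassEstimate:
    V_body: float        # mm^3
    V_mesothorax: float  # mm^3
    m_body: float        # g
    m_muscle: float      # g
    m_star_muscle: float


@dataclass
class FlightMetrics:
    b: float            # wingspan, mm (mirrored pair)
    S: float            # wing-pair area, mm^2
    c: float            # mean chord, mm
    AR: float


def _second_moments(points: np.ndarray):
    """Area, centroid and central second moments of a simple polygon."""
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    A = 0.5 * cross.sum()
    cx = np.sum((x + xn) * cross) / (6 * A)
    cy = np.sum((y + yn) * cross) / (6 * A)
    Ixx = np.sum((y ** 2 + y * yn + yn ** 2) * cross) / 12.0
    Iyy = np.sum((x ** 2 + x * xn + xn ** 2) * cross) / 12.0
    Ixy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross) / 24.0
    # shift to centroid
    Ixx -= A * cy ** 2
    Iyy -= A * cx ** 2
    Ixy -= A * cx * cy
    return A, np.array([cx, cy]), Ixx, Iyy, Ixy


def principal_axis_align(points: np.ndarray) -> np.ndarray:
    """Rotate a polygon so its long (principal) axis lies along x.

    Uses the area second-moment tensor, so the result does not depend on
    vertex density.
    """
    A, c, Ixx, Iyy, Ixy = _second_moments(points)
    cov = np.array([[Iyy, Ixy], [Ixy, Ixx]]) / A
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    if major[0] < 0:
        major = -major
    rot = np.array([[major[0], major[1]], [-major[1], major[0]]])
    return (points - c) @ rot.T


def wing_planform_metrics(outline: WingOutline) -> FlightMetrics:
    """Planform metrics of a mirrored wing pair.

    The wing is reoriented to its principal long axis; span ``b`` is twice
    the single-wing length (the body's width is excluded), ``S`` twice the
    single-wing area, ``c = S/b`` and ``AR = b^2/S``.
    """
    outline.validate_simple()
    area = abs(signed_area(outline.points))
    if area <= 0:
        raise GeometryError("degenerate outline with zero area")
    aligned = principal_axis_align(outline.points)
    length = float(aligned[:, 0].max() - aligned[:, 0].min())
    b = 2.0 * length
    S = 2.0 * area
    c = S / b
    return FlightMetrics(b=b, S=S, c=c, AR=b * b / S)


def body_volumes(meas: BodyMeasurements, shape_factors: dict | None = None) -> dict:
    """Geometric body-model volumes (mm^3).

    Pro- and mesothorax are ellipsoids of revolution about the body axis
    with circular cross-section of diameter ``w_thorax``; the abdomen is a
    cone tapering from thorax width.  Per-group multiplicative shape factors
    (``k_pt``, ``k_mt``, ``k_ab``) default to 1 and absorb the group-specific
    geometry adjustments.
    """
    k = {"k_pt": 1.0, "k_mt": 1.0, "k_ab": 1.0}
    if shape_factors:
        k.update(shape_factors)
    if any(v <= 0 for v in k.values()):
        raise ParameterError("shape factors must be positive")
    w2 = meas.w_thorax ** 2
    V_pt = np.pi / 6.0 * meas.l_pt * w2 * k["k_pt"]
    V_mt = np.pi / 6.0 * meas.l_mt * w2 * k["k_mt"]
    V_ab = np.pi / 12.0 * meas.l_abdomen * w2 * k["k_ab"]
    return {"V_prothorax": V_pt, "V_mesothorax": V_mt, "V_abdomen": V_ab,
            "V_body": V_pt + V_mt + V_ab}


def mass_estimates(volumes: dict) -> MassEstimate:
    """Masses from model volumes assuming the density of water."""
    V_body, V_mt = volumes["V_body"], volumes["V_mesothorax"]
    if V_body <= 0 or V_mt <= 0:
        raise ParameterError("volumes must be positive")
    if V_mt >= V_body:
        raise ParameterError("mesothorax volume must be smaller than body volume")
    m_body = V_body * MM3_TO_G
    m_muscle = V_mt * MM3_TO_G
    return MassEstimate(V_body=V_body, V_mesothorax=V_mt, m_body=m_body,
                        m_muscle=m_muscle, m_star_muscle=m_muscle / m_body)


def wing_loading(m_body_g: float, S_total_cm2: float) -> float:
    """Wing loading WL = body mass / total wing area, in g/cm^2."""
    if m_body_g <= 0 or S_total_cm2 <= 0:
        raise ParameterError("mass and area must be positive")
    return m_body_g / S_total_cm2


def relative_speed_ratio(wl_a: float, wl_b: float) -> float:
    """Flight-speed ratio U_b/U_a implied by U ~ sqrt(WL)."""
    if wl_a <= 0 or wl_b <= 0:
        raise ParameterError("wing loadings must be positive")
    return float(np.sqrt(wl_b / wl_a))


def taxon_flight_metrics(forewing: WingOutline,
                         combined: WingOutline | None,
                         meas: BodyMeasurements | None,
                         shape_factors: dict | None = None,
                         wl_area: str = "combined_pair") -> dict:
    """Full per-taxon flight-trait table.

    Computes forewing (and, when available, combined-wing) planform metrics,
    the body-model mass estimates, and wing loading.  ``wl_area`` selects
    which wing-pair area enters WL (``combined_pair`` by default, falling
    back to the forewing pair when no combined outline exists).
    """
    fw = wing_planform_metrics(forewing)
    out = {"b": fw.b, "S_forewing_pair": fw.S, "c_forewing": fw.c,
           "AR_forewing": fw.AR}
    cw = None
    if combined is not None:
        cw = wing_planform_metrics(combined)
        out.update({"b_combined": cw.b, "S_combined_pair": cw.S,
                    "AR_combined": cw.AR})
    if meas is not None:
        masses = mass_estimates(body_volumes(meas, shape_factors))
        out.update({"m_body": masses.m_body, "m_muscle": masses.m_muscle,
                    "m_star_muscle": masses.m_star_muscle})
        if wl_area == "combined_pair" and cw is not None:
            S_wl = cw.S
        else:
            S_wl = fw.S
        out["WL"] = wing_loading(masses.m_body, S_wl * MM2_TO_CM2)
    return out
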