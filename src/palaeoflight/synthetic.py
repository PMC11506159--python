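"""Synthetic palaeontinid cohort generator.

Builds complete synthetic fossil cohorts — parametric wing outlines with
exact labeled sub-regions (costal area, clavus, extended costal area), body
measurements, discrete character matrices and stratigraphic metadata — with
the statistical structure the downstream analyses assume: an "early" group
(suboval forewings, large hind wings, low wing loading) and a "late" group
(subtriangular forewings, reduced hind wings, high wing loading, and an
aspect-ratio/wingspan allometry absent in the early group).

Wing outline family
-------------------
A wing is a smooth closed curve built from a chordwise half-width profile
g(u) = u^p (1-u)^q (peak-normalized), u in [0, 1] along the long axis.  The
exponents interpolate with the ``triangularity`` parameter: at 0 the profile
is the ellipse (p = q = 1/2); at 1 the peak shifts toward the wing base and
the taper straightens, giving a subtriangular planform.  Leading and
trailing edges share the profile with an asymmetric amplitude split.
Sub-regions are cut from the polygon by straight lines whose positions are
solved so each region's area fraction matches its drawn target exactly
(to 1e-9), so area proportions are known by construction.

Default parameter values are the package's study conditions: cohort medians
of wing loading, aspect ratios, relative muscle mass and region proportions
are calibrated (solved once numerically) to the published group medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPolygon, Polygon

from palaeoflight.disparity import MISSING, CharacterMatrix, DisparityError
from palaeoflight.flight import BodyMeasurements
from palaeoflight.wing_geometry import ParameterError, WingOutline, signed_area

logger = logging.getLogger("palaeoflight")

GROUPS = ("early", "late", "dunstaniid")

#: stratigraphic interval vocabulary (oldest first)
INTERVALS = ("Late Triassic", "Early Jurassic", "Middle Jurassic",
             "Late Jurassic", "Early Cretaceous")

#: sampling weights over INTERVALS per group, patterned on the published
#: species tallies per epoch
INTERVAL_WEIGHTS = {
    "early": (5, 10, 38, 3, 2),
    "late": (0, 0, 0, 4, 26),
    "dunstaniid": (1, 0, 0, 0, 0),
}

#: leading-edge share of the total wing width
LEADING_EDGE_SHARE = 0.40

#: half-plane cut directions (degrees from the +y axis, toward the base)
COSTAL_CUT_DEG = 25.0
CLAVUS_CUT_DEG = 25.0


@dataclass
class WingShapeParams:
    """Parameters of one generated wing outline."""

    length: float               # mm, along the long axis
    aspect: float               # length / max width
    triangularity: float        # 0 = suboval ... 1 = subtriangular
    costal_fraction: float | None = None
    clavus_fraction: float | None = None
    peco_fraction: float | None = None
    n_points: int = 200
    noise_amp: float = 0.02     # smooth boundary perturbation amplitude

    def validate(self):
        for name in ("length", "aspect"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be positive and finite")
        if not 0.0 <= self.triangularity <= 1.0:
            raise ParameterError("triangularity must lie in [0, 1]")
        for name in ("costal_fraction", "clavus_fraction", "peco_fraction"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v < 1.0:
                raise ParameterError(f"{name} must lie in (0, 1)")
        if self.n_points < 64:
            raise ParameterError("n_points must be >= 64")


@dataclass
class CohortSpec:
    """Distributional description of one synthetic group.

    Linear dimensions are log-normal: ``*_median`` is the distribution
    median (mm) and ``*_log_sd`` the standard deviation on the natural-log
    scale.  ``allometric_slope`` couples log wing slenderness to log wing
    length (nonzero only in the late group by default).
    """

    group: str
    n_taxa: int
    # forewing
    length_median: float
    length_log_sd: float
    aspect_median: float
    aspect_log_sd: float
    allometric_slope: float
    triangularity_mean: float
    triangularity_sd: float
    costal_median: float
    costal_log_sd: float
    clavus_median: float
    clavus_log_sd: float
    peco_over_costal: float
    # hind wing
    fw_hw_median: float          # forewing : hind-wing length ratio
    fw_hw_log_sd: float
    hw_aspect_median: float
    hw_aspect_log_sd: float
    hw_triangularity: float
    # body (mm)
    w_thorax_median: float
    w_thorax_log_sd: float
    l_pt_median: float
    l_mt_median: float
    l_abdomen_median: float
    body_log_sd: float
    # discrete characters
    char_within_noise: float = 0.15
    seed: int | None = None

    def validate(self):
        if self.group not in GROUPS:
            raise ParameterError(f"unknown group {self.group!r}")
        if self.n_taxa < 1:
            raise ParameterError("n_taxa must be >= 1")
        positive = ("length_median", "aspect_median", "costal_median",
                    "clavus_median", "peco_over_costal", "fw_hw_median",
                    "hw_aspect_median", "w_thorax_median", "l_pt_median",
                    "l_mt_median", "l_abdomen_median")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("costal_median", "clavus_median"):
            if not 0 < getattr(self, name) < 1:
                raise ParameterError(f"{name} must lie in (0, 1)")


@dataclass
class SyntheticTaxon:
    taxon_id: str
    group: str
    forewing: WingOutline
    hindwing: WingOutline
    body: BodyMeasurements
    interval: str


# ---------------------------------------------------------------------------
# Wing outline construction
# ---------------------------------------------------------------------------


def _profile(u: np.ndarray, triangularity: float) -> np.ndarray:
    """Peak-normalized chordwise half-width profile."""
    p = 0.5 + 0.5 * triangularity
    q = 0.5 + 2.0 * triangularity
    ustar = p / (p + q)
    peak = ustar ** p * (1.0 - ustar) ** q
    return np.clip(u, 0, 1) ** p * np.clip(1.0 - u, 0, 1) ** q / peak


def _smooth_noise(u: np.ndarray, rng, amp: float) -> np.ndarray:
    """Low-order smooth perturbation vanishing at both wing tips."""
    if rng is None or amp <= 0:
        return np.ones_like(u)
    coef = rng.normal(0.0, 1.0, 3) / np.arange(1, 4)
    wave = sum(c * np.sin((k + 1) * np.pi * u) for k, c in enumerate(coef))
    return 1.0 + amp * wave


def _halfplane_cut_area(poly: Polygon, normal: np.ndarray, c: float) -> tuple:
    """Intersection of ``poly`` with the half-plane {p : normal . p >= c}."""
    minx, miny, maxx, maxy = poly.bounds
    diag = 4.0 * max(maxx - minx, maxy - miny, 1.0)
    nx, ny = normal
    tx, ty = -ny, nx
    p0 = np.array([nx, ny]) * c
    rect = Polygon([p0 + np.array([tx, ty]) * diag,
                    p0 - np.array([tx, ty]) * diag,
                    p0 - np.array([tx, ty]) * diag + np.array([nx, ny]) * diag,
                    p0 + np.array([tx, ty]) * diag + np.array([nx, ny]) * diag])
    inter = poly.intersection(rect)
    if inter.is_empty:
        return 0.0, None
    if isinstance(inter, MultiPolygon):
        inter = max(inter.geoms, key=lambda g: g.area)
    if inter.geom_type != "Polygon":
        return 0.0, None
    return inter.area, inter


def _cut_region(poly: Polygon, angle_deg: float, anterior: bool,
                target_fraction: float) -> np.ndarray:
    """Solve a straight-line cut so the cut-off region has the target area.

    ``anterior=True`` cuts toward the leading (+y) edge, otherwise toward
    the trailing (-y) edge; the cut plane tilts ``angle_deg`` toward the
    wing base so the region is basal.
    """
    a = np.deg2rad(angle_deg)
    normal = np.array([-np.sin(a), np.cos(a) if anterior else -np.cos(a)])
    verts = np.asarray(poly.exterior.coords)
    proj = verts @ normal
    lo, hi = proj.min(), proj.max()
    target = target_fraction * poly.area
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        area, _region = _halfplane_cut_area(poly, normal, mid)
        if area > target:
            lo = mid
        else:
            hi = mid
    area, region = _halfplane_cut_area(poly, normal, 0.5 * (lo + hi))
    if region is None:
        raise ParameterError("region cut failed; fraction too small?")
    pts = np.asarray(region.exterior.coords)[:-1]
    if signed_area(pts) < 0:
        pts = pts[::-1]
    return pts


def generate_wing_outline(params: WingShapeParams, rng=None,
                          wing: str = "forewing") -> WingOutline:
    """Generate a closed, simple wing outline with labeled sub-regions.

    The wing base sits at the origin, the tip at (+length, 0); the leading
    edge has positive y.  Increasing ``triangularity`` at fixed length and
    aspect moves the planform from suboval toward subtriangular.  Costal,
    clavus and extended-costal sub-polygons are cut so their area fractions
    equal the requested values by construction.
    """
    params.validate()
    L = params.length
    W = L / params.aspect
    n_half = params.n_points // 2
    # cosine spacing clusters vertices at base and tip
    psi = np.linspace(0.0, np.pi, n_half + 1)
    u = 0.5 * (1.0 - np.cos(psi))
    g = _profile(u, params.triangularity)
    g_le = g * _smooth_noise(u, rng, params.noise_amp)
    g_te = g * _smooth_noise(u, rng, params.noise_amp)
    x = u * L
    y_le = LEADING_EDGE_SHARE * W * g_le
    y_te = -(1.0 - LEADING_EDGE_SHARE) * W * g_te
    # counterclockwise: base -> tip along the trailing edge, back along the
    # leading edge (interior keeps left)
    lower = np.column_stack([x, y_te])
    upper = np.column_stack([x, y_le])[::-1]
    pts = np.vstack([lower, upper[1:-1]])
    outline = WingOutline(pts, wing=wing)
    outline.validate_simple()
    if wing == "forewing" and params.costal_fraction is not None:
        poly = outline.polygon
        regions = {}
        regions["costal"] = _cut_region(poly, COSTAL_CUT_DEG, True,
                                        params.costal_fraction)
        if params.clavus_fraction is not None:
            regions["clavus"] = _cut_region(poly, CLAVUS_CUT_DEG, False,
                                            params.clavus_fraction)
        if params.peco_fraction is not None:
            regions["peco"] = _cut_region(poly, COSTAL_CUT_DEG, True,
                                          params.peco_fraction)
        outline.regions = regions
    return outline


def default_hindwing_placement(forewing: WingOutline,
                               hindwing: WingOutline) -> tuple:
    """Default planar placement of the hind wing for the combined outline.

    The hind wing (generated base-at-origin like the forewing) is shifted
    slightly tipward and posteriorly so it underlaps the forewing's
    posterior margin, as in a coupled wing pair.
    """
    fw_te = -forewing.points[:, 1].min()      # trailing-edge half-depth
    hw_le = hindwing.points[:, 1].max()       # hind-wing leading half-depth
    length = forewing.points[:, 0].max() - forewing.points[:, 0].min()
    dx = 0.10 * length
    dy = -0.75 * (fw_te + hw_le)
    return 0.0, (dx, dy)


# ---------------------------------------------------------------------------
# Body measurements
# ---------------------------------------------------------------------------


def generate_body(group: str, rng, spec: CohortSpec) -> BodyMeasurements:
    """Draw one taxon's body dimensions from the group's distributions."""
    if group not in GROUPS:
        raise ParameterError(f"unknown group {group!r}")
    spec.validate()
    s = spec.body_log_sd
    w = spec.w_thorax_median * np.exp(rng.normal(0.0, spec.w_thorax_log_sd))
    l_pt = spec.l_pt_median * np.exp(rng.normal(0.0, s))
    l_mt = spec.l_mt_median * np.exp(rng.normal(0.0, s))
    l_ab = spec.l_abdomen_median * np.exp(rng.normal(0.0, s))
    return BodyMeasurements(w_thorax=w, l_pt=l_pt, l_mt=l_mt,
                            l_abdomen=l_ab, group=group)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _draw_taxon(spec: CohortSpec, idx: int, rng) -> SyntheticTaxon:
    g = spec.group
    # forewing size and slenderness (allometric coupling through length)
    zl = rng.normal(0.0, 1.0)
    length = spec.length_median * np.exp(spec.length_log_sd * zl)
    log_aspect = (np.log(spec.aspect_median)
                  + spec.allometric_slope * spec.length_log_sd * zl
                  + rng.normal(0.0, spec.aspect_log_sd))
    aspect = np.exp(log_aspect)
    tri = float(np.clip(rng.normal(spec.triangularity_mean,
                                   spec.triangularity_sd), 0.0, 1.0))
    costal = float(np.clip(
        spec.costal_median * np.exp(rng.normal(0.0, spec.costal_log_sd)),
        1e-3, 0.4))
    clavus = float(np.clip(
        spec.clavus_median * np.exp(rng.normal(0.0, spec.clavus_log_sd)),
        1e-3, 0.4))
    peco = float(np.clip(costal * spec.peco_over_costal, 1e-3, 0.5))
    fw = generate_wing_outline(WingShapeParams(
        length=length, aspect=aspect, triangularity=tri,
        costal_fraction=costal, clavus_fraction=clavus, peco_fraction=peco),
        rng=rng)
    # hind wing: the forewing:hind-wing length ratio respects the group rule
    # (early and dunstaniid <= 1.8, late > 1.8)
    ratio = spec.fw_hw_median * np.exp(rng.normal(0.0, spec.fw_hw_log_sd))
    if g == "late":
        ratio = max(ratio, 1.8 + 1e-6)
    else:
        ratio = min(ratio, 1.8)
    hw_aspect = spec.hw_aspect_median * np.exp(
        rng.normal(0.0, spec.hw_aspect_log_sd))
    hw = generate_wing_outline(WingShapeParams(
        length=length / ratio, aspect=hw_aspect,
        triangularity=spec.hw_triangularity), rng=rng, wing="hindwing")
    body = generate_body(g, rng, spec)
    weights = np.array(INTERVAL_WEIGHTS[g], dtype=float)
    interval = str(rng.choice(INTERVALS, p=weights / weights.sum()))
    return SyntheticTaxon(taxon_id=f"{g}_{idx:03d}", group=g, forewing=fw,
                          hindwing=hw, body=body, interval=interval)


def generate_cohort(specs, seed: int | None = None) -> list:
    """Generate a full synthetic cohort from one or more group specs.

    Reproducible: the same (specs, seed) yields an identical cohort.  Each
    spec may carry its own ``seed``; otherwise per-spec streams are spawned
    from ``seed``.
    """
    specs = list(specs)
    if not specs:
        raise ParameterError("need at least one CohortSpec")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    children = ss.spawn(len(specs))
    taxa = []
    for spec, child in zip(specs, children):
        spec.validate()
        rng = np.random.default_rng(
            spec.seed if spec.seed is not None else child)
        for i in range(spec.n_taxa):
            taxa.append(_draw_taxon(spec, i, rng))
    ids = [t.taxon_id for t in taxa]
    if len(set(ids)) != len(ids):
        raise ParameterError("duplicate taxon ids (same group label twice?)")
    return taxa


# ---------------------------------------------------------------------------
# Discrete character matrices
# ---------------------------------------------------------------------------


def generate_character_matrix(groups, n_chars: int = 86,
                              missing_frac: float = 0.2,
                              divergence: float = 0.5,
                              seed: int | None = None,
                              n_states: int = 3,
                              within_noise=0.15) -> CharacterMatrix:
    """Discrete character matrix with controlled between-group divergence.

    Each group has an archetype state vector; the two archetypes differ per
    character with probability ``divergence`` (0 makes all groups share one
    archetype, so taxa are exchangeable and group tests are null).  Each
    taxon resamples each character with its group's ``within_noise``
    probability (a scalar keeps groups exchangeable under divergence = 0; a
    per-group dict — as the pipeline uses, with wider early-group noise —
    makes the early group more disparate).  Missing cells are completely at
    random at rate ``missing_frac``.
    """
    groups = list(groups)
    if n_chars < 2:
        raise DisparityError("n_chars must be >= 2")
    if not 0.0 <= missing_frac < 1.0:
        raise DisparityError("missing_frac must lie in [0, 1)")
    if not 0.0 <= divergence <= 1.0:
        raise DisparityError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    names = list(dict.fromkeys(groups))
    base = rng.integers(0, n_states, n_chars)
    archetypes = {names[0]: base}
    for name in names[1:]:
        arch = base.copy()
        flip = rng.random(n_chars) < divergence
        shift = rng.integers(1, n_states, n_chars)
        arch[flip] = (arch[flip] + shift[flip]) % n_states
        archetypes[name] = arch
    rows = []
    for g in groups:
        w = within_noise if np.isscalar(within_noise) else within_noise.get(g, 0.15)
        row = archetypes[g].copy()
        resample = rng.random(n_chars) < w
        row[resample] = rng.integers(0, n_states, int(resample.sum()))
        rows.append(row)
    states = np.array(rows, dtype=int)
    if missing_frac > 0:
        mask = rng.random(states.shape) < missing_frac
        for i in range(mask.shape[0]):            # keep >= 1 observed state
            if mask[i].all():
                mask[i, rng.integers(0, n_chars)] = False
        states = np.where(mask, MISSING, states)
    taxa = [f"{g}_{i:03d}" for i, g in enumerate(groups)]
    return CharacterMatrix(states=states, taxa=taxa, groups=groups)


# ---------------------------------------------------------------------------
# Default published-calibration cohort specs
# ---------------------------------------------------------------------------

# Calibration constants solved once numerically so that the measured cohort
# medians reproduce the published group medians (WL, AR_forewing,
# AR_combined, m*_muscle, S*_costal, S*_clavus) and, for the late group,
# the log(AR)-log(b) Pearson correlation.  See docs/methods.md.
DEFAULT_CALIBRATION = {
    "early": dict(
        length_median=40.0, length_log_sd=0.20,
        aspect_median=2.048, aspect_log_sd=0.10, allometric_slope=0.0,
        triangularity_mean=0.30, triangularity_sd=0.08,
        costal_median=0.081, costal_log_sd=0.12,
        clavus_median=0.085, clavus_log_sd=0.12,
        peco_over_costal=1.8,
        fw_hw_median=1.45, fw_hw_log_sd=0.05,
        hw_aspect_median=1.57, hw_aspect_log_sd=0.08,
        hw_triangularity=0.15,
        w_thorax_median=17.95, w_thorax_log_sd=0.10,
        l_pt_median=4.0, l_mt_median=18.782, l_abdomen_median=24.0,
        body_log_sd=0.10,
        char_within_noise=0.25,
    ),
    "late": dict(
        length_median=42.0, length_log_sd=0.20,
        aspect_median=1.990, aspect_log_sd=0.17, allometric_slope=0.80,
        triangularity_mean=0.75, triangularity_sd=0.08,
        costal_median=0.054, costal_log_sd=0.12,
        clavus_median=0.049, clavus_log_sd=0.12,
        peco_over_costal=1.8,
        fw_hw_median=1.83, fw_hw_log_sd=0.04,
        hw_aspect_median=0.80, hw_aspect_log_sd=0.08,
        hw_triangularity=0.30,
        w_thorax_median=23.40, w_thorax_log_sd=0.10,
        l_pt_median=4.0, l_mt_median=29.75, l_abdomen_median=20.0,
        body_log_sd=0.10,
        char_within_noise=0.10,
    ),
    "dunstaniid": dict(
        length_median=35.0, length_log_sd=0.18,
        aspect_median=1.95, aspect_log_sd=0.10, allometric_slope=0.0,
        triangularity_mean=0.15, triangularity_sd=0.07,
        costal_median=0.12, costal_log_sd=0.12,
        clavus_median=0.10, clavus_log_sd=0.12,
        peco_over_costal=1.8,
        fw_hw_median=1.40, fw_hw_log_sd=0.05,
        hw_aspect_median=1.50, hw_aspect_log_sd=0.08,
        hw_triangularity=0.10,
        w_thorax_median=16.0, w_thorax_log_sd=0.10,
        l_pt_median=4.0, l_mt_median=16.0, l_abdomen_median=24.0,
        body_log_sd=0.10,
        char_within_noise=0.15,
    ),
}


def default_cohort_spec(group: str, n_taxa: int,
                        seed: int | None = None, **overrides) -> CohortSpec:
    """CohortSpec with the default published-calibration constants."""
    if group not in DEFAULT_CALIBRATION:
        raise ParameterError(f"unknown group {group!r}")
    kw = dict(DEFAULT_CALIBRATION[group])
    kw.update(overrides)
    return CohortSpec(group=group, n_taxa=n_taxa, seed=seed, **kw)


# ---------------------------------------------------------------------------
# Cohort serialization
# ---------------------------------------------------------------------------


def write_cohort(taxa, outdir):
    """Write a cohort to disk: TPS + CSV outlines, body CSV, metadata CSV.

    Layout: ``forewings.tps`` / ``hindwings.tps`` (one record per taxon),
    per-taxon ``outlines/<id>_<wing>.csv`` point lists, ``bodies.csv``
    (columns w_thorax_mm, l_pt_mm, l_mt_mm, l_abdomen_mm) and
    ``taxa.csv`` (taxon_id, group, interval).
    """
    import pathlib

    import pandas as pd

    from palaeoflight.wing_geometry import write_tps

    outdir = pathlib.Path(outdir)
    (outdir / "outlines").mkdir(parents=True, exist_ok=True)
    write_tps(outdir / "forewings.tps",
              {t.taxon_id: t.forewing for t in taxa})
    write_tps(outdir / "hindwings.tps",
              {t.taxon_id: t.hindwing for t in taxa})
    for t in taxa:
        for wing in ("forewing", "hindwing"):
            pts = getattr(t, wing).points
            pd.DataFrame(pts, columns=["x_mm", "y_mm"]).to_csv(
                outdir / "outlines" / f"{t.taxon_id}_{wing}.csv", index=False)
        for name, reg in t.forewing.regions.items():
            pd.DataFrame(reg, columns=["x_mm", "y_mm"]).to_csv(
                outdir / "outlines" / f"{t.taxon_id}_region_{name}.csv",
                index=False)
    pd.DataFrame([{
        "taxon_id": t.taxon_id,
        "w_thorax_mm": t.body.w_thorax, "l_pt_mm": t.body.l_pt,
        "l_mt_mm": t.body.l_mt, "l_abdomen_mm": t.body.l_abdomen,
    } for t in taxa]).to_csv(outdir / "bodies.csv", index=False)
    pd.DataFrame([{
        "taxon_id": t.taxon_id, "group": t.group, "interval": t.interval,
    } for t in taxa]).to_csv(outdir / "taxa.csv", index=False)
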