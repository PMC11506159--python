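"""Discrete-character distances, PCoA morphospace and disparity metrics.

Given a taxa x characters matrix of integer states with missing data, this
module computes the two character distances standard in fossil disparity
work — the Maximum Observable Rescaled Distance (MORD, bounded [0, 1]) and
the Generalized Euclidean Distance (GED, with pairwise mean imputation for
incomparable cells) — ordinates the distance matrix by principal
coordinates analysis (optionally with the Cailliez correction for negative
eigenvalues), and summarizes group morphospace occupation by the sum of
variances (SOV), sum of ranges (SOR) and median distance from centroid
(MDC), with bootstrap uncertainty, rarefaction and PERMANOVA group tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("palaeoflight")


class DisparityError(ValueError):
    """Raised on invalid character or distance data."""


MISSING = -1   # internal code for missing ("?") cells


# ---------------------------------------------------------------------------
# Character matrix
# ---------------------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """Discrete morphological characters for a set of taxa.

    ``states`` is an integer (n_taxa, n_chars) array with ``-1`` marking
    missing cells.  ``ordering`` gives per-character type, ``"unordered"``
    (default) or ``"ordered"``.
    """

    states: np.ndarray
    taxa: list
    groups: list = field(default_factory=list)
    ordering: list = field(default_factory=list)

    def __post_init__(self):
        s = np.asarray(self.states, dtype=int)
        if s.ndim != 2 or s.shape[0] < 2:
            raise DisparityError("need a 2-D matrix with >= 2 taxa")
        if np.any(s < MISSING):
            raise DisparityError("states must be nonnegative (or -1 missing)")
        if np.any(np.all(s == MISSING, axis=1)):
            raise DisparityError("every taxon needs >= 1 observed state")
        if len(self.taxa) != s.shape[0]:
            raise DisparityError("taxon labels must match matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise DisparityError("duplicate taxon ids")
        if not self.ordering:
            self.ordering = ["unordered"] * s.shape[1]
        self.states = s

    @property
    def n_taxa(self) -> int:
        return self.states.shape[0]

    @property
    def n_chars(self) -> int:
        return self.states.shape[1]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with an incomparability mask."""

    values: np.ndarray
    method: str
    taxa: list = field(default_factory=list)
    mask: np.ndarray | None = None   # True where the pair was incomparable

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DisparityError("distance matrix must be square")
        if np.nanmax(np.abs(v - v.T)) > 1e-12:
            raise DisparityError("distance matrix must be symmetric")
        self.values = v


def pairwise_distance(m: CharacterMatrix, method: str = "MORD") -> DistanceMatrix:
    """MORD or GED distances between all taxon pairs.

    MORD: sum of per-character differences over mutually observed
    characters divided by the maximum possible difference over those same
    characters (unordered characters contribute 0/1 with max 1; ordered
    contribute |state difference| with max equal to the character's observed
    state range).  Pairs with no comparable character are masked.

    GED: squared per-character differences summed over all characters, with
    each incomparable cell imputed by the pair's mean observed difference,
    then square-rooted (Wills' generalized Euclidean distance).
    """
    method = method.upper()
    if method not in ("MORD", "GED"):
        raise DisparityError(f"unknown distance method {method!r}")
    s = m.states
    n, k = s.shape
    obs = s != MISSING
    ordered = np.array([o == "ordered" for o in m.ordering])
    # per-character maximum difference
    smax = np.where(obs, s, np.iinfo(int).min).max(axis=0)
    smin = np.where(obs, s, np.iinfo(int).max).min(axis=0)
    char_range = np.maximum(smax - smin, 0)
    max_diff = np.where(ordered, char_range, 1).astype(float)
    never = ~obs.any(axis=0)
    max_diff[never] = 0.0

    d = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            comp = obs[i] & obs[j]
            diff = np.abs(s[i] - s[j]).astype(float)
            diff = np.where(ordered, diff, (diff > 0).astype(float))
            if method == "MORD":
                denom = max_diff[comp].sum()
                if not comp.any() or denom == 0:
                    mask[i, j] = mask[j, i] = True
                    d[i, j] = d[j, i] = np.nan
                    continue
                val = diff[comp].sum() / denom
            else:
                if comp.any():
                    mean_diff = diff[comp].mean()
                else:
                    mask[i, j] = mask[j, i] = True
                    mean_diff = np.nan
                sq = np.where(comp, diff ** 2, mean_diff ** 2)
                val = np.sqrt(sq.sum())
            d[i, j] = d[j, i] = val
    if np.all(np.isnan(d[np.triu_indices(n, 1)])):
        raise DisparityError("all taxon pairs are incomparable")
    n_masked = int(mask[np.triu_indices(n, 1)].sum())
    if n_masked:
        logger.warning("pairwise_distance: %d incomparable pair(s) masked",
                       n_masked)
    return DistanceMatrix(values=d, method=method, taxa=list(m.taxa), mask=mask)


def impute_masked(d: DistanceMatrix) -> DistanceMatrix:
    """Replace masked (incomparable) entries by the matrix-wide mean distance."""
    v = d.values.copy()
    nan = np.isnan(v)
    if nan.any():
        fill = np.nanmean(v[np.triu_indices(v.shape[0], 1)])
        v[nan] = fill
        np.fill_diagonal(v, 0.0)
        logger.info("impute_masked: %d entries imputed with mean distance %.4f",
                    int(nan.sum()), fill)
    return DistanceMatrix(values=v, method=d.method, taxa=d.taxa, mask=d.mask)


# ---------------------------------------------------------------------------
# Principal coordinates analysis
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    coordinates: np.ndarray        # (n, k) for axes with positive eigenvalue
    eigenvalues: np.ndarray        # all eigenvalues, descending
    proportion: np.ndarray         # proportion of variation per retained axis
    correction: str = "none"
    taxa: list = field(default_factory=list)


def _gower_center(dsq: np.ndarray) -> np.ndarray:
    n = dsq.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ dsq @ J


def cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant making a dissimilarity matrix Euclidean.

    Largest real eigenvalue of the 2n x 2n special matrix of Cailliez
    (1983); adding it to every off-diagonal dissimilarity removes all
    negative PCoA eigenvalues.
    """
    n = d.shape[0]
    d1 = _gower_center(d ** 2)
    d2 = _gower_center(d)
    upper = np.hstack([np.zeros((n, n)), 2.0 * d1])
    lower = np.hstack([-np.eye(n), -4.0 * d2])
    ev = np.linalg.eigvals(np.vstack([upper, lower]))
    return float(max(ev.real.max(), 0.0))


def pcoa(d: DistanceMatrix, correction: str = "none",
         eig_tol: float = 1e-9) -> Ordination:
    """Principal coordinates analysis of a distance matrix.

    Double-centers the squared distances and eigen-decomposes; axes with
    eigenvalue <= tolerance are dropped from the coordinates.  With
    ``correction="cailliez"`` the additive constant is applied when
    negative eigenvalues are present.
    """
    v = d.values
    if np.isnan(v).any():
        raise DisparityError("distance matrix has masked entries; impute first")
    if np.max(np.abs(v - v.T)) > 1e-12:
        raise DisparityError("distance matrix must be symmetric")
    applied = "none"
    B = _gower_center(v ** 2)
    evals = np.linalg.eigvalsh(B)
    scale = max(abs(evals).max(), 1.0)
    if correction == "cailliez" and evals.min() < -eig_tol * scale:
        c = cailliez_constant(v)
        v = v + c
        np.fill_diagonal(v, 0.0)
        B = _gower_center(v ** 2)
        applied = "cailliez"
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > eig_tol * max(abs(evals).max(), 1.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    total = evals[pos].sum()
    prop = evals[pos] / total if total > 0 else evals[pos]
    return Ordination(coordinates=coords, eigenvalues=evals,
                      proportion=prop, correction=applied, taxa=d.taxa)


# ---------------------------------------------------------------------------
# Disparity metrics
# ---------------------------------------------------------------------------


@dataclass
class DisparitySummary:
    group: str
    metric: str
    estimate: float
    bootstrap: np.ndarray
    ci_low: float
    ci_high: float


def disparity_metrics(points: np.ndarray, axes: int | None = None) -> dict:
    """SOV, SOR and MDC of a group's morphospace coordinates.

    SOV is the sum of per-axis sample variances (n-1 denominator), SOR the
    sum of per-axis ranges, MDC the median Euclidean distance from the group
    centroid.  A single point gives (0, 0, 0).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if p.shape[0] < 1:
        raise DisparityError("need at least one point")
    if axes is not None:
        if axes > p.shape[1]:
            raise DisparityError("requested more axes than available")
        p = p[:, :axes]
    if p.shape[0] == 1:
        return {"SOV": 0.0, "SOR": 0.0, "MDC": 0.0}
    sov = float(p.var(axis=0, ddof=1).sum())
    sor = float((p.max(axis=0) - p.min(axis=0)).sum())
    centroid = p.mean(axis=0)
    mdc = float(np.median(np.linalg.norm(p - centroid, axis=1)))
    return {"SOV": sov, "SOR": sor, "MDC": mdc}


def bootstrap_disparity(points: np.ndarray, metric: str, n_boot: int = 1000,
                        seed: int | None = None, group: str = "") -> DisparitySummary:
    """Bootstrap distribution and percentile CI of one disparity metric."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if n_boot < 1:
        raise DisparityError("n_boot must be >= 1")
    if p.shape[0] < 2:
        raise DisparityError("bootstrap needs >= 2 points")
    metric = metric.upper()
    if metric not in ("SOV", "SOR", "MDC"):
        raise DisparityError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)
    n = p.shape[0]
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        boot[i] = disparity_metrics(p[idx])[metric]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return DisparitySummary(group=group, metric=metric,
                            estimate=disparity_metrics(p)[metric],
                            bootstrap=boot, ci_low=float(lo), ci_high=float(hi))


def rarefaction_curve(points: np.ndarray, metric: str, sizes,
                      reps: int = 100, seed: int | None = None) -> dict:
    """Disparity metric distributions for subsamples without replacement."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    metric = metric.upper()
    rng = np.random.default_rng(seed)
    n = p.shape[0]
    out = {}
    for size in sizes:
        if size > n:
            raise DisparityError(f"subsample size {size} exceeds n={n}")
        vals = np.empty(reps)
        for r in range(reps):
            idx = rng.choice(n, size=size, replace=False)
            vals[r] = disparity_metrics(p[idx])[metric]
        out[int(size)] = vals
    return out


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def permanova(d: DistanceMatrix, labels, n_perm: int = 999,
              seed: int | None = None) -> dict:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F from the among/within partition of squared distances
    (Anderson 2001); p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).
    """
    v = d.values
    if np.isnan(v).any():
        raise DisparityError("distance matrix has masked entries; impute first")
    labels = np.asarray(labels)
    names, inv = np.unique(labels, return_inverse=True)
    if len(names) < 2:
        raise DisparityError("PERMANOVA needs >= 2 groups")
    if np.any(np.bincount(inv) < 2):
        raise DisparityError("each group needs >= 2 members")
    if n_perm < 99:
        raise DisparityError("n_perm must be >= 99")
    n = v.shape[0]
    a = len(names)
    dsq = v ** 2
    iu = np.triu_indices(n, 1)
    ss_total = dsq[iu].sum() / n

    def f_stat(inv_labels):
        ss_within = 0.0
        for g in range(a):
            m = inv_labels == g
            ng = m.sum()
            sub = dsq[np.ix_(m, m)]
            ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = f_stat(inv)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if f_stat(rng.permutation(inv)) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return {"F": float(f_obs), "p": float(p), "n_perm": n_perm}


# ---------------------------------------------------------------------------
# NEXUS I/O (dendropy-backed)
# ---------------------------------------------------------------------------


def read_nexus(path, collapse_polymorphic: bool = True) -> CharacterMatrix:
    """Read a standard (morphological) NEXUS matrix.

    States are digits 0-9, missing is "?".  Polymorphic codings such as
    "(01)" are collapsed to missing by default (logged).
    """
    import dendropy

    cm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    taxa = [t.label for t in cm.taxon_namespace]
    rows = []
    n_poly = 0
    for t in cm.taxon_namespace:
        row = []
        for cell in cm[t]:
            sym = cell.symbol
            if sym is None or len(str(cell)) > 1:
                # polymorphic / ambiguous state set
                if collapse_polymorphic:
                    n_poly += 1
                    row.append(MISSING)
                    continue
                raise DisparityError("polymorphic codings present")
            if sym in ("?", "-"):
                row.append(MISSING)
            else:
                row.append(int(sym))
        rows.append(row)
    if n_poly:
        logger.info("read_nexus: %d polymorphic cells collapsed to missing",
                    n_poly)
    return CharacterMatrix(states=np.array(rows, dtype=int), taxa=taxa)


def write_nexus(m: CharacterMatrix, path):
    """Write the character matrix as a standard NEXUS file."""
    max_state = max(int(m.states.max()), 1)
    symbols = "".join(str(i) for i in range(max_state + 1))
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_chars};\n")
        fh.write(f'  FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=?;\n')
        fh.write("  MATRIX\n")
        width = max(len(t) for t in m.taxa) + 4
        for t, row in zip(m.taxa, m.states):
            cells = "".join("?" if s == MISSING else str(s) for s in row)
            label = f"'{t}'"      # quoted: preserves underscores verbatim
            fh.write(f"    {label:<{width}}{cells}\n")
        fh.write("  ;\nEND;\n")


def write_distance_csv(d: DistanceMatrix, path):
    import pandas as pd

    taxa = d.taxa or [f"t{i}" for i in range(d.values.shape[0])]
    pd.DataFrame(d.values, index=taxa, columns=taxa).to_csv(path)
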