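"""Group-comparison and allometry statistics.

Welch's unequal-variance t test, Pearson correlation, log-log ANCOVA with a
group x slope interaction, residual-assumption checks (Shapiro-Wilk
normality, Bartlett variance homogeneity) and median percent differences.
These are thin, contract-enforcing wrappers over scipy/statsmodels with the
edge-case behavior the pipeline relies on (zero-variance samples, rounding
conventions) made explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf


class StatsError(ValueError):
    """Raised when a statistical precondition fails."""


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise StatsError("sample contains non-finite values")
    return x


def welch_t(x, y) -> dict:
    """Two-sided Welch's t test with Welch-Satterthwaite df.

    Degenerate inputs: two zero-variance samples with equal means give
    t = 0, p = 1; zero variance with different means is reported with
    ``infinite=True`` (t is +/-inf, p = 0).
    """
    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("welch_t needs n >= 2 per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    dm = x.mean() - y.mean()
    if vx == 0 and vy == 0:
        if dm == 0:
            return {"t": 0.0, "df": float(len(x) + len(y) - 2), "p": 1.0,
                    "infinite": False}
        return {"t": np.inf if dm > 0 else -np.inf, "df": np.nan, "p": 0.0,
                "infinite": True}
    sx, sy = vx / len(x), vy / len(y)
    se = np.sqrt(sx + sy)
    t = dm / se
    df = (sx + sy) ** 2 / (sx ** 2 / (len(x) - 1) + sy ** 2 / (len(y) - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p), "infinite": False}


def pearson_cor(x, y) -> dict:
    """Pearson correlation with a t-transform p-value on n-2 df."""
    x, y = _clean(x), _clean(y)
    if len(x) != len(y):
        raise StatsError("samples must be paired")
    if len(x) < 3:
        raise StatsError("pearson_cor needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise StatsError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue)}


@dataclass
class AllometryFit:
    """Per-group log-log allometry of aspect ratio on wingspan."""

    slopes: dict
    intercepts: dict
    residual_sd: float
    interaction_F: float
    interaction_p: float
    group_pearson: dict


def ancova_interaction(log_b, log_ar, groups) -> AllometryFit:
    """ANCOVA of log(AR) on log(b) with a group interaction term.

    Fits ``log_ar ~ log_b * group`` by OLS; the interaction F test asks
    whether the allometric slopes differ between groups.  Per-group OLS
    slopes/intercepts and Pearson correlations are returned alongside.
    """
    log_b, log_ar = _clean(log_b), _clean(log_ar)
    groups = np.asarray(groups)
    if not (len(log_b) == len(log_ar) == len(groups)):
        raise StatsError("inputs must be aligned")
    names = pd.unique(groups)
    if len(names) != 2:
        raise StatsError("ancova_interaction expects exactly 2 groups")
    for g in names:
        m = groups == g
        if m.sum() < 3:
            raise StatsError(f"group {g!r} needs at least 3 points")
        if np.std(log_b[m]) == 0:
            raise StatsError(f"group {g!r} has a degenerate (constant) covariate")
    df = pd.DataFrame({"y": log_ar, "x": log_b, "g": groups})
    fit = smf.ols("y ~ x * C(g)", data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    row = [i for i in anova.index if ":" in i][0]
    slopes, intercepts, pearson = {}, {}, {}
    for g in names:
        m = groups == g
        sl, ic = np.polyfit(log_b[m], log_ar[m], 1)
        slopes[g], intercepts[g] = float(sl), float(ic)
        pearson[g] = pearson_cor(log_b[m], log_ar[m])
    resid_sd = float(np.sqrt(fit.mse_resid))
    return AllometryFit(slopes=slopes, intercepts=intercepts,
                        residual_sd=resid_sd,
                        interaction_F=float(anova.loc[row, "F"]),
                        interaction_p=float(anova.loc[row, "PR(>F)"]),
                        group_pearson=pearson)


def assumption_checks(residuals, groups=None, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk normality and Bartlett variance-homogeneity checks.

    ``groups`` (optional labels aligned with ``residuals``) enables the
    Bartlett test; without it only normality is checked.  Raw p-values are
    reported together with a pass flag at ``alpha``.
    """
    res = _clean(residuals)
    if len(res) < 3:
        raise StatsError("assumption checks need n >= 3")
    if res.std() == 0:
        raise StatsError("constant sample")
    W, p_norm = sps.shapiro(res)
    out = {"shapiro_W": float(W), "shapiro_p": float(p_norm),
           "normality_ok": bool(p_norm > alpha)}
    if groups is not None:
        groups = np.asarray(groups)
        samples = [res[groups == g] for g in pd.unique(groups)]
        if any(len(s) < 2 for s in samples):
            raise StatsError("each group needs n >= 2 for Bartlett's test")
        K2, p_var = sps.bartlett(*samples)
        out.update({"bartlett_K2": float(K2), "bartlett_p": float(p_var),
                    "variance_homogeneity_ok": bool(p_var > alpha)})
    return out


def median_percent_difference(x, y, digits: int | None = 0) -> float:
    """Percent difference of medians, 100 * (med(y) - med(x)) / med(x).

    ``digits`` rounds for reporting (nearest integer by default); pass
    ``None`` for the unrounded value.
    """
    x, y = _clean(x), _clean(y)
    if len(x) == 0 or len(y) == 0:
        raise StatsError("both groups must be nonempty")
    mx, my = float(np.median(x)), float(np.median(y))
    if mx == 0:
        raise StatsError("baseline median is zero")
    pct = 100.0 * (my - mx) / mx
    if digits is None:
        return pct
    return float(round(pct, digits))
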