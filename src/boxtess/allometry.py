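"""Allometric scaling of carapace and scute variables against surface area.

Carapace surface area (SA) is the body-size variable.  Dimensioned
variables are regressed as ln(y) on ln(SA) by ordinary least squares
(slope = scaling exponent, 95% t-based confidence interval); scute
counts use a Poisson GLM with log link whose slope and CI are
exp-transformed back to the response scale.  Fitted exponents feed the
size normalization y / SA^slope, and a region × SA interaction test
checks whether edge and flat scutes may share one pooled exponent.

Isometric references against an area-based size variable: 0.5 for
lengths, 1.0 for areas, 1.5 for volumes, 0 for dimensionless ratios,
−1.0 for Gaussian curvature, −0.5 for mean curvature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

#: expected slope vs SA by physical dimension of the variable
ISOMETRY_REFERENCE = {
    "length": 0.5, "height": 0.5, "width": 0.5,
    "scute_width": 0.5, "thickness": 0.5,
    "area": 1.0, "volume": 1.5,
    "aspect_ratio": 0.0, "n_scutes": 1.0,
    "cgs": -1.0, "cms": -0.5,
}


@dataclass
class ScalingFit:
    variable: str
    model: str  # "loglog_ols" | "poisson_loglink"
    slope: float
    intercept: float
    ci95: tuple[float, float]
    residuals: np.ndarray
    n: int
    specimen_ids: list = field(default_factory=list)

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.slope <= hi):
            raise ValueError("slope must lie inside its confidence interval")


def fit_loglog(sa, y, variable: str = "y",
               specimen_ids=None) -> ScalingFit:
    """OLS of ln(y) on ln(SA): slope, intercept, 95% CI, residuals."""
    sa = np.asarray(sa, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(sa) != len(y):
        raise ValueError("sa and y must have equal length")
    if len(sa) < 3:
        raise ValueError("need at least 3 specimens")
    bad = ~((sa > 0) & (y > 0))
    if np.any(bad):
        which = (np.asarray(specimen_ids)[bad].tolist()
                 if specimen_ids is not None
                 else np.flatnonzero(bad).tolist())
        raise ValueError(f"non-positive values for specimens {which}")
    X = sm.add_constant(np.log(sa))
    fit = sm.OLS(np.log(y), X).fit()
    lo, hi = fit.conf_int(alpha=0.05)[1]
    return ScalingFit(variable=variable, model="loglog_ols",
                      slope=float(fit.params[1]),
                      intercept=float(fit.params[0]),
                      ci95=(float(lo), float(hi)),
                      residuals=np.asarray(fit.resid), n=len(sa),
                      specimen_ids=list(specimen_ids)
                      if specimen_ids is not None else [])


def fit_scute_count(sa, counts, ci_method: str = "profile",
                    log_sa: bool = False,
                    specimen_ids=None) -> ScalingFit:
    """Poisson GLM (log link) of scute counts on SA, back-transformed.

    The predictor is untransformed SA by default (``log_sa`` switches to
    ln SA); the reported slope and CI are exp() of the linear-scale
    coefficient, so a slope of 1.00 means counts independent of size.
    CI by profile likelihood (``ci_method="wald"`` for Wald).
    """
    sa = np.asarray(sa, dtype=float)
    counts = np.asarray(counts)
    if np.any(counts != np.round(counts)) or np.any(counts < 0):
        raise ValueError("counts must be non-negative integers")
    counts = counts.astype(float)
    x = np.log(sa) if log_sa else sa
    X = sm.add_constant(x)
    fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    beta = float(fit.params[1])
    if ci_method == "wald":
        lo, hi = fit.conf_int(alpha=0.05)[1]
    elif ci_method == "profile":
        lo, hi = _profile_ci_poisson(counts, x, beta)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    mu = np.asarray(fit.fittedvalues)
    resid = counts - mu
    return ScalingFit(variable="n_scutes", model="poisson_loglink",
                      slope=float(np.exp(beta)),
                      intercept=float(fit.params[0]),
                      ci95=(float(np.exp(lo)), float(np.exp(hi))),
                      residuals=resid, n=len(sa),
                      specimen_ids=list(specimen_ids)
                      if specimen_ids is not None else [])


def _profile_ci_poisson(counts, x, beta_hat, alpha=0.05):
    """Profile-likelihood CI for the slope of a 2-parameter Poisson GLM."""

    def loglik_at(beta):
        # refit the intercept with the slope fixed via an offset
        off = beta * x
        m = sm.GLM(counts, np.ones((len(counts), 1)),
                   family=sm.families.Poisson(), offset=off).fit()
        return float(m.llf)

    ll_max = loglik_at(beta_hat)
    cut = ll_max - 0.5 * stats.chi2.ppf(1 - alpha, df=1)

    def g(beta):
        return loglik_at(beta) - cut

    # bracket outward from the MLE
    se = max(abs(beta_hat) * 0.5, 1e-6)
    lo_b = beta_hat - se
    for _ in range(60):
        if g(lo_b) < 0:
            break
        lo_b = beta_hat - 2 * (beta_hat - lo_b)
    hi_b = beta_hat + se
    for _ in range(60):
        if g(hi_b) < 0:
            break
        hi_b = beta_hat + 2 * (hi_b - beta_hat)
    lo = optimize.brentq(g, lo_b, beta_hat, xtol=1e-12)
    hi = optimize.brentq(g, beta_hat, hi_b, xtol=1e-12)
    return lo, hi


def normalize_by_sa(values, sa, slope: float) -> np.ndarray:
    """Size-correct values by dividing by SA^slope (per specimen)."""
    sa = np.asarray(sa, dtype=float)
    if np.any(sa <= 0):
        raise ValueError("SA must be positive")
    return np.asarray(values, dtype=float) / sa ** slope


def residuals_by_geometry(fit: ScalingFit, classes) -> pd.DataFrame:
    """Residuals grouped by simplified carapace geometry class.

    Returns one row per specimen (class, residual) plus per-class
    median/min/max summary columns, the data behind the residual
    strip plots.
    """
    classes = list(classes)
    if len(classes) != len(fit.residuals):
        raise ValueError("classes must cover all specimens in the fit")
    df = pd.DataFrame({
        "specimen": (fit.specimen_ids if fit.specimen_ids
                     else list(range(len(classes)))),
        "geometry_class": classes,
        "residual": fit.residuals,
    })
    summary = df.groupby("geometry_class")["residual"].agg(
        ["median", "min", "max", "count"])
    return df.join(summary, on="geometry_class", rsuffix="_class")


def region_interaction_test(sa, y_flat, y_edge) -> float:
    """p-value of the SA × region interaction on ln(median y).

    OLS of ln(y) on ln(SA) × region over the stacked flat and edge
    per-specimen medians (2 rows per specimen).  A non-significant
    interaction (alpha = 0.05) justifies pooling both regions into one
    scaling exponent.  Returns NaN with a warning when the fit is
    degenerate (zero residual variance).
    """
    sa = np.asarray(sa, dtype=float)
    y_flat = np.asarray(y_flat, dtype=float)
    y_edge = np.asarray(y_edge, dtype=float)
    if not (len(sa) == len(y_flat) == len(y_edge)):
        raise ValueError("need flat and edge medians for every specimen")
    if np.any(~np.isfinite(y_flat)) or np.any(~np.isfinite(y_edge)):
        raise ValueError("missing region medians")
    lx = np.log(np.concatenate([sa, sa]))
    ly = np.log(np.concatenate([y_flat, y_edge]))
    region = np.concatenate([np.zeros(len(sa)), np.ones(len(sa))])
    X = sm.add_constant(np.column_stack([lx, region, lx * region]))
    fit = sm.OLS(ly, X).fit()
    if fit.ssr <= 1e-12 * max(1.0, float(np.var(ly)) * len(ly)):
        warnings.warn("interaction test degenerate: zero residual "
                      "variance, p-value not identifiable", stacklevel=2)
        return float("nan")
    return float(fit.pvalues[3])
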