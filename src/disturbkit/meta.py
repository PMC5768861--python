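"""Meta-regression of disturbance severity on intensity across events.

Each record is one species' severity for one disturbance event, both on the
log10 return-period scale: x = log10 intensity return period (years),
y = log10 severity return period (years).  After an inclusion filter
(rare, large-scale events; species with generation times of 1-10 years),
the relationship is fitted with a generalized linear model — by default
gamma-distributed errors with a log link, the family/link pair selected by
AIC/BIC among configurable candidates — and interrogated for confidence
and prediction bands, the severity-intensity crossover, residual patterns,
and subgroup (e.g. mobile vs. sessile) differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "RECORD_COLUMNS",
    "InclusionThresholds",
    "GLMFit",
    "CrossoverResult",
    "validate_records",
    "inclusion_filter",
    "fit_glm",
    "select_model",
    "predict_bands",
    "crossover",
    "residual_table",
    "subgroup_fit",
]

#: Schema of a severity-intensity records table (one row per event x species).
RECORD_COLUMNS = [
    "event_id",
    "species_id",
    "event_type",
    "x_log10_intensity_rp",
    "y_log10_severity_rp",
    "ci_low",
    "ci_high",
    "mobility",
    "generation_time_years",
    "spatial_extent_km2",
]

_FAMILIES = {"gaussian": sm.families.Gaussian, "gamma": sm.families.Gamma}
_LINKS = {"identity": sm.families.links.Identity, "log": sm.families.links.Log}

#: Default family/link candidates for information-criterion selection.
DEFAULT_CANDIDATES = [
    ("gaussian", "identity"),
    ("gaussian", "log"),
    ("gamma", "identity"),
    ("gamma", "log"),
]


@dataclass(frozen=True)
class InclusionThresholds:
    """Study inclusion rules: rare, large-scale events; 1-10 yr generations."""

    min_intensity_rp: float = 20.0  # years
    min_generation_time: float = 1.0  # years
    max_generation_time: float = 10.0  # years
    min_spatial_extent: float = 10.0  # km^2


@dataclass
class GLMFit:
    """A fitted severity-intensity GLM.

    The fitted mean is ``linkinv(beta0 + beta1 * x)``; dispersion is the
    Pearson estimate.  ``aic`` and ``bic`` are computed from the same
    log-likelihood with ``k = n_coef + 1`` parameters (coefficients plus
    dispersion), so ``bic - aic == k * (ln n - 2)`` exactly.
    """

    family: str
    link: str
    beta0: float
    beta1: float
    se: tuple[float, float]
    p_values: tuple[float, float]
    dispersion: float
    llf: float
    aic: float
    bic: float
    n: int
    x_max: float
    cov_params: np.ndarray
    result: object = field(repr=False, default=None)

    def mean(self, x: np.ndarray) -> np.ndarray:
        eta = self.beta0 + self.beta1 * np.asarray(x, dtype=float)
        return np.exp(eta) if self.link == "log" else eta


@dataclass(frozen=True)
class CrossoverResult:
    """Where the fitted mean severity return period equals intensity's.

    ``x_star`` is the smallest positive root of exp(beta0 + beta1*x) = x;
    ``roots`` lists every root found on the search range (a convex mean
    curve can meet the identity twice: a down-crossing, then the
    up-crossing where severity starts to exceed intensity).
    """

    found: bool
    x_star: float | None = None  # log10 years
    years: float | None = None  # 10**x_star
    roots: tuple[float, ...] = ()


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    df = records.copy()
    for col in ("x_log10_intensity_rp", "y_log10_severity_rp"):
        df[col] = df[col].astype(float)
        if (df[col].dropna() < 0).any():
            raise ValueError(f"{col} must be non-negative (return periods >= 1 year)")
    return df


def inclusion_filter(
    records: pd.DataFrame,
    thresholds: InclusionThresholds = InclusionThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the study inclusion rules, logging every rejection.

    Keeps records with intensity return period >= 20 years, generation
    time within [1, 10] years, and spatial extent >= 10 km^2 (defaults).
    Records with missing metadata are rejected as ``incomplete``.

    Returns ``(kept, rejections)``; rejections carry the failed rule.
    """
    records = validate_records(records)
    tol = 1e-9
    kept_idx, rejections = [], []
    for idx, row in records.iterrows():
        rp = 10.0 ** row["x_log10_intensity_rp"]
        gen = row["generation_time_years"]
        area = row["spatial_extent_km2"]
        reason = None
        if any(pd.isna(v) for v in (row["x_log10_intensity_rp"], gen, area)):
            reason = "incomplete"
        elif rp < thresholds.min_intensity_rp - tol:
            reason = f"intensity return period {rp:.3g} < {thresholds.min_intensity_rp} years"
        elif gen < thresholds.min_generation_time - tol:
            reason = f"generation time {gen:.3g} < {thresholds.min_generation_time} years"
        elif gen > thresholds.max_generation_time + tol:
            reason = f"generation time {gen:.3g} > {thresholds.max_generation_time} years"
        elif area < thresholds.min_spatial_extent - tol:
            reason = f"spatial extent {area:.3g} < {thresholds.min_spatial_extent} km^2"
        if reason is None:
            kept_idx.append(idx)
        else:
            rejections.append(
                {
                    "event_id": row["event_id"],
                    "species_id": row["species_id"],
                    "reason": reason,
                }
            )
    return records.loc[kept_idx], pd.DataFrame(
        rejections, columns=["event_id", "species_id", "reason"]
    )


def fit_glm(
    records: pd.DataFrame,
    family: str = "gamma",
    link: str = "log",
    zero_nudge: float | None = 1e-6,
) -> GLMFit:
    """Fit severity (response) on intensity (explanatory) by ML.

    ``zero_nudge`` handles the gamma family's positivity requirement:
    responses exactly 0 (a 1-year severity return period) are raised to
    this value with a warning; pass ``None`` to make them an error
    instead.  Negative responses are always an error.
    """
    records = validate_records(records)
    if len(records) < 3:
        raise ValueError("need at least 3 records to fit the GLM")
    x = records["x_log10_intensity_rp"].to_numpy(dtype=float)
    y = records["y_log10_severity_rp"].to_numpy(dtype=float).copy()
    if family == "gamma":
        zero = y == 0.0
        if zero.all():
            # nudging is for occasional ties at a 1-year return period, not
            # for a response with no positive values at all
            raise ValueError(
                "gamma family requires positive response; all severity values are zero"
            )
        if zero.any():
            ids = records.loc[zero, ["event_id", "species_id"]].astype(str).agg("/".join, axis=1)
            if zero_nudge is None:
                raise ValueError(
                    "gamma family requires positive response; zero severity for "
                    f"records: {', '.join(ids)}"
                )
            warnings.warn(
                f"{zero.sum()} zero severity value(s) nudged to {zero_nudge} for the "
                f"gamma family (records: {', '.join(ids)})",
                stacklevel=2,
            )
            y[zero] = zero_nudge
    if family not in _FAMILIES or link not in _LINKS:
        raise ValueError(f"unknown family/link {family!r}/{link!r}")
    with warnings.catch_warnings():
        # statsmodels warns that non-canonical links are less tested
        warnings.simplefilter("ignore")
        fam = _FAMILIES[family](link=_LINKS[link]())
        model = sm.GLM(y, sm.add_constant(x), family=fam)
        try:
            res = model.fit()
        except Exception as exc:  # noqa: BLE001 - surfaced with context
            raise RuntimeError(f"GLM fit failed for {family}/{link}: {exc}") from exc
    if not res.converged:
        raise RuntimeError(
            f"GLM did not converge for {family}/{link} after {res.fit_history['iteration']} "
            f"IRLS iterations; deviance trace: {res.fit_history['deviance']}"
        )
    n = len(y)
    k = 3  # intercept, slope, dispersion
    llf = float(res.llf)
    return GLMFit(
        family=family,
        link=link,
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        se=(float(res.bse[0]), float(res.bse[1])),
        p_values=(float(res.pvalues[0]), float(res.pvalues[1])),
        dispersion=float(res.scale),  # Pearson estimate
        llf=llf,
        aic=2 * k - 2 * llf,
        bic=k * math.log(n) - 2 * llf,
        n=n,
        x_max=float(np.max(x)),
        cov_params=np.asarray(res.cov_params()),
        result=res,
    )


def select_model(
    records: pd.DataFrame,
    candidates: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, GLMFit]:
    """Rank candidate family/link pairs by AIC (BIC reported alongside).

    Returns the ranking table and the AIC-smallest fit; a ``bic_disagrees``
    flag marks the chosen row when BIC prefers a different candidate.
    Candidates that fail to fit are kept in the table with NaN criteria.
    """
    candidates = DEFAULT_CANDIDATES if candidates is None else candidates
    rows, fits = [], {}
    for fam, link in candidates:
        try:
            fit = fit_glm(records, family=fam, link=link)
            fits[(fam, link)] = fit
            rows.append({"family": fam, "link": link, "aic": fit.aic, "bic": fit.bic})
        except (RuntimeError, ValueError) as exc:
            rows.append(
                {"family": fam, "link": link, "aic": np.nan, "bic": np.nan, "error": str(exc)}
            )
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    if not fits:
        details = "; ".join(
            f"{r['family']}/{r['link']}: {r['error']}" for r in rows if r.get("error")
        )
        raise RuntimeError(f"all candidate models failed to fit ({details})")
    chosen_key = min(fits, key=lambda key: fits[key].aic)
    bic_key = min(fits, key=lambda key: fits[key].bic)
    table["chosen"] = [
        (r["family"], r["link"]) == chosen_key for r in table.to_dict("records")
    ]
    table["bic_disagrees"] = table["chosen"] & (chosen_key != bic_key)
    return table, fits[chosen_key]


def predict_bands(
    fit: GLMFit,
    x_grid: np.ndarray,
    level: float = 0.95,
) -> pd.DataFrame:
    """Mean curve with confidence and prediction bands over ``x_grid``.

    The CI comes from the coefficient covariance on the linear-predictor
    scale, mapped through the inverse link.  The PI is the response
    quantile (gamma or gaussian) at the fitted mean and Pearson
    dispersion, widened where needed to contain the CI so that mean
    uncertainty is never understated; hence CI ⊆ PI pointwise.
    Grid points outside [0, max observed x + 1] trigger an extrapolation
    warning.
    """
    x = np.asarray(x_grid, dtype=float)
    if np.any((x < 0) | (x > fit.x_max + 1)):
        warnings.warn(
            "extrapolation: x-grid extends outside [0, max observed x + 1]", stacklevel=2
        )
    design = np.column_stack([np.ones_like(x), x])
    eta = design @ np.array([fit.beta0, fit.beta1])
    var_eta = np.einsum("ij,jk,ik->i", design, fit.cov_params, design)
    se_eta = np.sqrt(np.maximum(var_eta, 0.0))
    z = stats.norm.ppf((1 + level) / 2)
    inv = np.exp if fit.link == "log" else (lambda v: v)
    mean = inv(eta)
    ci_low, ci_high = inv(eta - z * se_eta), inv(eta + z * se_eta)

    q_lo, q_hi = (1 - level) / 2, (1 + level) / 2
    phi = fit.dispersion
    if fit.family == "gamma":
        if phi <= 0:
            pi_low, pi_high = mean.copy(), mean.copy()
        else:
            shape = 1.0 / phi
            pi_low = stats.gamma.ppf(q_lo, a=shape, scale=mean * phi)
            pi_high = stats.gamma.ppf(q_hi, a=shape, scale=mean * phi)
    else:
        sd = math.sqrt(max(phi, 0.0))
        pi_low, pi_high = mean - z * sd, mean + z * sd
    pi_low = np.minimum(pi_low, ci_low)
    pi_high = np.maximum(pi_high, ci_high)
    return pd.DataFrame(
        {
            "x": x,
            "mean": mean,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "pi_low": pi_low,
            "pi_high": pi_high,
        }
    )


def crossover(fit: GLMFit, x_hi: float = 10.0) -> CrossoverResult:
    """Smallest x where the fitted mean severity equals the intensity.

    Solves exp(beta0 + beta1*x) = x on (0, ``x_hi``] (log10-years scale)
    by bracketing and root refinement to 1e-8.  No sign change means the
    mean curve never meets the identity line: a ``no crossover`` result,
    not an error.
    """
    if fit.link != "log":
        raise ValueError("crossover is defined for the log link")
    if fit.beta1 < 0:
        raise ValueError("crossover expects a non-negative slope")

    def f(x: float) -> float:
        return math.exp(fit.beta0 + fit.beta1 * x) - x

    grid = np.linspace(1e-6, x_hi, 4001)
    vals = np.array([f(g) for g in grid])
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) <= 0)[0]
    if len(sign_change) == 0:
        return CrossoverResult(found=False)
    roots = []
    for i in sign_change:
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        else:
            roots.append(float(brentq(f, grid[i], grid[i + 1], xtol=1e-10, rtol=1e-14)))
    x_star = roots[0]
    return CrossoverResult(
        found=True, x_star=x_star, years=10.0**x_star, roots=tuple(roots)
    )


def residual_table(fit: GLMFit, records: pd.DataFrame) -> pd.DataFrame:
    """Response residuals y - fitted mean, per record, sorted by x."""
    records = validate_records(records)
    x = records["x_log10_intensity_rp"].to_numpy(dtype=float)
    y = records["y_log10_severity_rp"].to_numpy(dtype=float)
    out = records[["event_id", "species_id", "event_type"]].copy()
    out["x"] = x
    out["y"] = y
    out["fitted"] = fit.mean(x)
    out["residual"] = y - out["fitted"]
    return out.sort_values("x").reset_index(drop=True)


def subgroup_fit(
    records: pd.DataFrame,
    grouping_key: str = "mobility",
    family: str = "gamma",
    link: str = "log",
    alpha: float = 0.05,
    min_n: int = 3,
) -> dict[str, dict]:
    """Independent GLM fit per subgroup with slope significance flags.

    Returns ``{group: {"fit": GLMFit, "slope_p": float,
    "significant": bool}}``; groups with fewer than ``min_n`` records are
    skipped with a warning.
    """
    records = validate_records(records)
    out: dict[str, dict] = {}
    for group, sub in records.groupby(grouping_key):
        if len(sub) < min_n:
            warnings.warn(
                f"subgroup {group!r} has only {len(sub)} record(s); skipped", stacklevel=2
            )
            continue
        fit = fit_glm(sub, family=family, link=link)
        p_slope = fit.p_values[1]
        out[str(group)] = {
            "fit": fit,
            "slope_p": p_slope,
            "significant": p_slope < alpha,
        }
    return out
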