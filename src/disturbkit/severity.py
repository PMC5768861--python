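"""Severity of a disturbance's impact on one population, as a return period.

Severity is measured through the annual population growth rate
r_t = ln(N_{t+1} / N_t).  The disturbance-year rate is compared with the
rates under normal (non-disturbance) conditions by a single-case
standardized effect size

    ES = (r_pd - mean(r_n)) / sd(r_n),

where r_pd is the growth rate across the disturbance (census immediately
before -> immediately after) and r_n are the normal-condition rates.  The
severity return period is 1 / Phi(ES): assuming normal-condition rates are
normally distributed, Phi(ES) is the probability of an equally bad or worse
year arising by chance, and its inverse is the average waiting time for one.

Normal-condition rates are cleaned in two ways before use: census intervals
flagged as influenced by other documented events or stresses are dropped,
and a post-event recovery trend (e.g. exponential re-growth after a crash)
is removed by an iterative regression filter.

Uncertainty in ES is quantified by a bias-corrected percentile bootstrap
over the normal-condition rates.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IntervalStatus",
    "AbundanceSeries",
    "GrowthRateSeries",
    "EffectSizeResult",
    "SeverityEstimate",
    "annualize",
    "growth_rates",
    "trend_filter",
    "select_normal_years",
    "effect_size",
    "bootstrap_ci",
    "severity_return_period",
    "es_from_return_period",
    "estimate_severity",
]


class IntervalStatus(str, enum.Enum):
    NORMAL = "normal"
    DISTURBANCE_YEAR = "disturbance_year"
    EXCLUDED_OTHER_STRESS = "excluded_other_stress"
    EXCLUDED_TREND = "excluded_trend"
    MISSING = "missing"


@dataclass
class AbundanceSeries:
    """A census time series for one species population plus event context.

    Parameters
    ----------
    data
        DataFrame with columns ``year`` (int), optional ``season`` (str),
        ``abundance`` (float >= 0).  Rows within a year are assumed to be
        in chronological order.
    species_id
        Identifier of the population/species.
    event_year
        Calendar year containing the focal disturbance; the census of
        ``event_year`` is the first post-event census (after season
        selection), so the disturbance interval is
        ``event_year - 1 -> event_year``.
    excluded_periods
        Year ranges ``(start, end)`` inclusive, reported in the source as
        influenced by other events or stresses.
    post_event_season
        Optional explicit season tag of the first post-event census; when
        absent it is inferred as the season of the first record in the
        earliest census year >= event_year.
    """

    data: pd.DataFrame
    species_id: str
    event_year: int
    excluded_periods: list[tuple[int, int]] = field(default_factory=list)
    generation_time: float | None = None
    mobility: str | None = None
    habitat: str | None = None
    spatial_extent_km2: float | None = None
    post_event_season: str | None = None

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "season" not in df.columns:
            df["season"] = None
        missing = {"year", "abundance"} - set(df.columns)
        if missing:
            raise ValueError(f"abundance data missing columns: {sorted(missing)}")
        df["year"] = df["year"].astype(int)
        df["abundance"] = df["abundance"].astype(float)
        if (df["abundance"].dropna() < 0).any():
            raise ValueError("abundances must be non-negative")
        self.data = df[["year", "season", "abundance"]]
        years = df["year"]
        if not years.min() <= self.event_year <= years.max():
            raise ValueError(
                f"event_year {self.event_year} outside census span "
                f"[{years.min()}, {years.max()}]"
            )
        for start, end in self.excluded_periods:
            if start > end:
                raise ValueError(f"excluded period ({start}, {end}) reversed")
            if start <= self.event_year - 1 <= end or start <= self.event_year <= end:
                raise ValueError(
                    "excluded_periods must not cover the censuses bracketing the event"
                )


@dataclass
class GrowthRateSeries:
    """Annual log growth rates with per-interval status labels.

    ``intervals`` has columns ``start_year``, ``r``, ``status``; each row is
    the interval ``start_year -> start_year + 1``.  Exactly one interval has
    status ``disturbance_year``; its rate is ``r_pd``.
    """

    intervals: pd.DataFrame
    r_pd: float

    def __post_init__(self) -> None:
        n_dist = (self.intervals["status"] == IntervalStatus.DISTURBANCE_YEAR).sum()
        if n_dist != 1:
            raise ValueError(f"expected exactly one disturbance-year interval, got {n_dist}")

    @property
    def normal_rates(self) -> np.ndarray:
        mask = self.intervals["status"] == IntervalStatus.NORMAL
        rates = self.intervals.loc[mask, "r"].to_numpy(dtype=float)
        return rates[np.isfinite(rates)]


@dataclass(frozen=True)
class EffectSizeResult:
    """Standardized single-case effect size with bootstrap CI bounds.

    The bias-corrected interval is not guaranteed to contain the point
    estimate, so no such invariant is enforced.
    """

    es: float
    n_normal: int
    mean_normal: float
    sd_normal: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class SeverityEstimate:
    """Severity return period (years), its log10, and transformed CI."""

    return_period: float
    log10_return_period: float
    occurrence_probability: float
    ci_low: float | None = None
    ci_high: float | None = None
    no_decline: bool = False


def annualize(ab: AbundanceSeries) -> AbundanceSeries:
    """Reduce to one abundance per year; zeros become missing.

    When several seasonal censuses exist per year, the season matching the
    first census after the disturbance event is kept.  Abundances within a
    (year, season) cell are averaged; an average of zero is treated as a
    missing census.  Years with no census in the matching season are
    missing, not errors.
    """
    df = ab.data
    seasons = df["season"].dropna().unique()
    if len(seasons) > 1:
        season = ab.post_event_season
        if season is None:
            post = df[df["year"] >= ab.event_year]
            if post.empty:
                raise ValueError("no census at or after the event year")
            first_year = post["year"].min()
            season = post.loc[post["year"] == first_year, "season"].iloc[0]
        df = df[df["season"] == season]
        if df.empty:
            raise ValueError(f"no census in post-event season {season!r}")
    by_year = df.groupby("year", as_index=False)["abundance"].mean()
    by_year.loc[by_year["abundance"] == 0.0, "abundance"] = np.nan
    by_year["season"] = None
    return replace(ab, data=by_year[["year", "season", "abundance"]])


def growth_rates(ab: AbundanceSeries) -> GrowthRateSeries:
    """Compute r_t = ln(N_{t+1}/N_t) for consecutive census years.

    Operates on an annualized series.  Intervals touching a missing census
    (absent year, zero-turned-NaN) get status ``missing``.  The interval
    ``event_year - 1 -> event_year`` is the disturbance year; if either of
    its censuses is missing the disturbance-year rate is undefined and an
    error is raised.
    """
    df = annualize(ab).data if ab.data["year"].duplicated().any() else ab.data
    abund = df.set_index("year")["abundance"]
    years = np.arange(abund.index.min(), abund.index.max())
    rows = []
    r_pd = None
    for t in years:
        n0 = abund.get(t, np.nan)
        n1 = abund.get(t + 1, np.nan)
        is_dist = t == ab.event_year - 1
        if np.isnan(n0) or np.isnan(n1) or n0 == 0 or n1 == 0:
            if is_dist:
                raise ValueError(
                    "disturbance-year growth rate undefined: a census bracketing "
                    f"the event ({t} or {t + 1}) is missing or zero"
                )
            rows.append((t, np.nan, IntervalStatus.MISSING))
            continue
        r = math.log(n1 / n0)
        status = IntervalStatus.DISTURBANCE_YEAR if is_dist else IntervalStatus.NORMAL
        if is_dist:
            r_pd = r
        rows.append((t, r, status))
    if r_pd is None:
        raise ValueError("disturbance-year growth rate undefined: event interval absent")
    intervals = pd.DataFrame(rows, columns=["start_year", "r", "status"])
    return GrowthRateSeries(intervals=intervals, r_pd=r_pd)


def trend_filter(
    post_event_abundances: list[tuple[int, float]], alpha: float = 0.05
) -> tuple[list[tuple[int, float]], list[dict]]:
    """Strip a significant post-event abundance trend, oldest census first.

    Fits OLS abundance ~ year; while the slope is significant at ``alpha``
    and at least 3 points remain, the oldest point is dropped and the
    regression refitted.  Fewer than 3 points are returned untested (with
    a warning if the loop exhausted the data).

    Returns the retained points and a removal log of
    ``{"year", "abundance", "p_value"}`` entries.
    """
    points = sorted(post_event_abundances)
    removals: list[dict] = []
    exhausted = False
    while len(points) >= 3:
        yrs = np.array([p[0] for p in points], dtype=float)
        ab = np.array([p[1] for p in points], dtype=float)
        if np.ptp(ab) == 0.0:  # flat: slope 0 by definition, linregress p is nan
            break
        res = stats.linregress(yrs, ab)
        if res.pvalue >= alpha or not np.isfinite(res.pvalue):
            break
        removed = points.pop(0)
        removals.append(
            {"year": removed[0], "abundance": removed[1], "p_value": float(res.pvalue)}
        )
        exhausted = len(points) < 3
    if exhausted:
        warnings.warn(
            "post-event trend removal exhausted the data; remaining "
            f"{len(points)} points retained untested",
            stacklevel=2,
        )
    return points, removals


def select_normal_years(
    g: GrowthRateSeries, ab: AbundanceSeries, alpha: float = 0.05
) -> GrowthRateSeries:
    """Label which growth-rate intervals count as normal conditions.

    Intervals overlapping a reported other-stress period are excluded;
    the post-event trend filter (on the second and subsequent post-event
    censuses) excludes intervals that touch a removed census.  At least 2
    normal-condition rates must survive.
    """
    intervals = g.intervals.copy()
    normal = intervals["status"] == IntervalStatus.NORMAL

    for start, end in ab.excluded_periods:
        overlap = (intervals["start_year"] <= end) & (intervals["start_year"] + 1 >= start)
        intervals.loc[normal & overlap, "status"] = IntervalStatus.EXCLUDED_OTHER_STRESS

    abund = ab.data.groupby("year")["abundance"].mean()
    stress_years = {
        y for start, end in ab.excluded_periods for y in range(start, end + 1)
    }
    post = [
        (int(y), float(v))
        for y, v in abund.items()
        if y >= ab.event_year + 1 and np.isfinite(v) and y not in stress_years
    ]
    _, removals = trend_filter(post, alpha=alpha)
    removed_years = {entry["year"] for entry in removals}
    if removed_years:
        normal = intervals["status"] == IntervalStatus.NORMAL
        touches = intervals["start_year"].isin(removed_years) | (
            intervals["start_year"] + 1
        ).isin(removed_years)
        intervals.loc[normal & touches, "status"] = IntervalStatus.EXCLUDED_TREND

    out = GrowthRateSeries(intervals=intervals, r_pd=g.r_pd)
    if len(out.normal_rates) < 2:
        raise ValueError(
            f"insufficient normal-condition data: {len(out.normal_rates)} rate(s) survive"
        )
    return out


def effect_size(g: GrowthRateSeries) -> EffectSizeResult:
    """Single-case standardized effect size of the disturbance year.

    ES = (r_pd - mean(r_n)) / sd(r_n) with the sample (n-1) standard
    deviation of the normal-condition rates.
    """
    rates = g.normal_rates
    if len(rates) < 2:
        raise ValueError("need at least 2 normal-condition growth rates")
    mean_n = float(np.mean(rates))
    sd_n = float(np.std(rates, ddof=1))
    # identical rates give sd ~ 1e-17 from round-off, not exactly 0
    if sd_n == 0.0 or np.all(rates == rates[0]):
        raise ValueError("zero variability under normal conditions")
    return EffectSizeResult(
        es=(g.r_pd - mean_n) / sd_n,
        n_normal=len(rates),
        mean_normal=mean_n,
        sd_normal=sd_n,
    )


def _bc_interval(boot: np.ndarray, point: float, level: float = 0.95) -> tuple[float, float]:
    """Bias-corrected (BC, not BCa) percentile interval."""
    b = len(boot)
    prop_less = np.clip(np.mean(boot < point), 1.0 / (b + 1), 1.0 - 1.0 / (b + 1))
    z0 = stats.norm.ppf(prop_less)
    z_lo, z_hi = stats.norm.ppf([(1 - level) / 2, (1 + level) / 2])
    a_lo = stats.norm.cdf(2 * z0 + z_lo)
    a_hi = stats.norm.cdf(2 * z0 + z_hi)
    lo, hi = np.quantile(boot, [a_lo, a_hi])
    return float(lo), float(hi)


def bootstrap_ci(
    g: GrowthRateSeries,
    n_boot: int = 10_000,
    seed: int | None = None,
    level: float = 0.95,
    max_degenerate_frac: float = 0.15,
) -> EffectSizeResult:
    """Bias-corrected bootstrap CI for the effect size.

    The normal-condition rates are resampled with replacement ``n_boot``
    times (r_pd held fixed) and ES recomputed for each resample.
    Degenerate resamples (zero standard deviation) are redrawn, with a
    logged count; tie-heavy data whose degenerate fraction exceeds
    ``max_degenerate_frac`` are refused.  The default leaves headroom for
    the smallest admissible sample — three distinct rates have an
    irreducible all-equal-resample probability of 1/9.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    point = effect_size(g)
    rates = g.normal_rates
    rng = np.random.default_rng(seed)
    n = len(rates)

    samples = rng.choice(rates, size=(n_boot, n), replace=True)
    n_degenerate = 0
    while True:
        # all-equal resamples are degenerate (sd is 0 up to round-off)
        bad = (samples == samples[:, :1]).all(axis=1)
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        n_degenerate += n_bad
        if n_degenerate > max_degenerate_frac * n_boot:
            raise ValueError(
                f"bootstrap degenerate-resample rate exceeds "
                f"{max_degenerate_frac:.0%} ({n_degenerate} redraws out of "
                f"{n_boot} target draws)"
            )
        samples[bad] = rng.choice(rates, size=(n_bad, n), replace=True)
    boot_es = (g.r_pd - samples.mean(axis=1)) / samples.std(axis=1, ddof=1)
    if n_degenerate:
        warnings.warn(f"{n_degenerate} degenerate bootstrap resamples redrawn", stacklevel=2)
    lo, hi = _bc_interval(boot_es, point.es, level=level)
    return replace(point, ci_low=lo, ci_high=hi, n_boot=n_boot, seed=seed)


def _es_to_probability(es: float, n_normal: int | None, small_sample: bool) -> float:
    if small_sample:
        if n_normal is None or n_normal < 2:
            raise ValueError("small-sample mode needs n_normal >= 2")
        scale = math.sqrt((n_normal + 1) / n_normal)
        return float(stats.t.cdf(es / scale, df=n_normal - 1))
    return float(stats.norm.cdf(es))


def severity_return_period(
    es_result: EffectSizeResult | float,
    small_sample: bool = False,
) -> SeverityEstimate:
    """Map an effect size to a severity return period.

    The occurrence probability of an equally severe or worse year is the
    lower-tail normal probability Phi(ES) (declines are negative ES), and
    the return period its inverse.  CI bounds, when present, are pushed
    through the same map; a more negative ES bound gives the larger
    return-period bound.  Non-negative ES means no decline was seen; the
    return period then lies in (1, 2] and the result is flagged.

    ``small_sample=True`` switches to a t-based probability with
    ``n_normal - 1`` degrees of freedom and an ``(n+1)/n`` variance
    inflation, a conservative option for very short normal records.
    """
    if isinstance(es_result, EffectSizeResult):
        es, n_norm = es_result.es, es_result.n_normal
        ci_low_es, ci_high_es = es_result.ci_low, es_result.ci_high
    else:
        es, n_norm = float(es_result), None
        ci_low_es = ci_high_es = None
    if not np.isfinite(es):
        raise ValueError("effect size must be finite")
    p = _es_to_probability(es, n_norm, small_sample)
    rp = 1.0 / p
    ci_low = ci_high = None
    if ci_low_es is not None and ci_high_es is not None:
        # ES interval maps order-reversed onto the return-period scale
        ci_low = 1.0 / _es_to_probability(ci_high_es, n_norm, small_sample)
        ci_high = 1.0 / _es_to_probability(ci_low_es, n_norm, small_sample)
    return SeverityEstimate(
        return_period=rp,
        log10_return_period=math.log10(rp),
        occurrence_probability=p,
        ci_low=ci_low,
        ci_high=ci_high,
        no_decline=es >= 0.0,
    )


def es_from_return_period(return_period: float) -> float:
    """Inverse of the severity map: ES with 1/Phi(ES) = return_period."""
    if return_period < 1.0:
        raise ValueError("return period must be >= 1 year")
    return float(stats.norm.ppf(1.0 / return_period))


def estimate_severity(
    ab: AbundanceSeries,
    n_boot: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    small_sample: bool = False,
) -> tuple[EffectSizeResult, SeverityEstimate, GrowthRateSeries]:
    """Full severity pipeline for one series: annualize through return period."""
    annual = annualize(ab)
    g = growth_rates(annual)
    g = select_normal_years(g, annual, alpha=alpha)
    es = bootstrap_ci(g, n_boot=n_boot, seed=seed)
    sev = severity_return_period(es, small_sample=small_sample)
    return es, sev, g
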