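"""Return-period estimation for the physical intensity of disturbance events.

The strength of a disturbance's physical forcing (wind speed, snow depth,
precipitation deficit, ...) is expressed on a common dimensionless scale:
the *return period*, the average interval in years between events at least
as extreme, equal to the inverse of the annual occurrence probability.

Three estimation routes are provided, matching how the forcing is recorded:

* annual *aggregate* measures (averages, cumulative totals) — a normal law,
  falling back to a lognormal after a Shapiro–Wilk gate;
* annual *extreme* measures (block maxima/minima, threshold-day counts) —
  a generalized extreme value (GEV) law fitted by maximum likelihood;
* *rare events* without an annual force record (tsunamis, eruptions) —
  record length divided by the number of events of equal or greater size.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MeasureKind",
    "Tail",
    "ForceSeries",
    "RareEventRecord",
    "IntensityEstimate",
    "choose_distribution",
    "normal_return_period",
    "gev_return_period",
    "historical_return_period",
    "estimate_intensity",
]


class MeasureKind(str, enum.Enum):
    """How the annual force measurement summarizes the year."""

    AGGREGATE = "aggregate"  # average or cumulative value
    EXTREME = "extreme"  # maximum, minimum, or threshold-based count


class Tail(str, enum.Enum):
    """Which tail of the force distribution is harmful."""

    UPPER = "upper"
    LOWER = "lower"


@dataclass(frozen=True)
class ForceSeries:
    """Annual force-strength measurements for one recording station/event.

    Parameters
    ----------
    years
        Calendar years, unique and strictly increasing.
    values
        Force measurements in their native physical unit (the unit is
        irrelevant here: return periods are invariant under affine
        rescaling).
    measure_kind
        Whether each annual value is an aggregate (average/cumulative) or
        an extreme (max/min/threshold count); decides the candidate law.
    harmful_tail
        The direction in which larger departures are more damaging.
    label
        Free-text description, carried through to outputs.
    """

    years: np.ndarray
    values: np.ndarray
    measure_kind: MeasureKind
    harmful_tail: Tail
    label: str = ""

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "measure_kind", MeasureKind(self.measure_kind))
        object.__setattr__(self, "harmful_tail", Tail(self.harmful_tail))
        if years.ndim != 1 or values.ndim != 1 or years.shape != values.shape:
            raise ValueError("years and values must be 1-D and equal length")
        if len(years) < 2:
            raise ValueError("force series needs at least 2 annual values")
        if len(np.unique(years)) != len(years) or np.any(np.diff(years) <= 0):
            raise ValueError("years must be unique and strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("force values must be finite")

    def __len__(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class RareEventRecord:
    """Historical evidence for a rare event: coverage length and event count.

    ``record_length`` is the span of the historical record in years and
    ``n_events`` the number of documented events of equal or greater
    magnitude within it.
    """

    record_length: float
    n_events: int

    def __post_init__(self) -> None:
        if not self.record_length > 0:
            raise ValueError("record_length must be positive")
        if self.n_events < 0 or int(self.n_events) != self.n_events:
            raise ValueError("n_events must be a non-negative integer")


@dataclass(frozen=True)
class IntensityEstimate:
    """A fitted intensity return period with its provenance.

    ``return_period * occurrence_probability == 1`` by construction
    (for ``method='historical'`` the probability is ``n_events /
    record_length``, which coincides with the inverse return period).
    """

    return_period: float
    log10_return_period: float
    method: str
    fit_params: dict = field(default_factory=dict)
    occurrence_probability: float = float("nan")

    @classmethod
    def from_probability(cls, p: float, method: str, fit_params: dict) -> "IntensityEstimate":
        if not 0.0 < p <= 1.0:
            raise ValueError(
                f"occurrence probability {p!r} outside (0, 1]; "
                "event value lies beyond the numerical support of the fitted law"
            )
        rp = 1.0 / p
        if rp < 1.0:  # cannot happen for p<=1; guard kept for subclass laws
            warnings.warn("return period below 1 year clamped to 1", stacklevel=3)
            rp = 1.0
        return cls(
            return_period=rp,
            log10_return_period=math.log10(rp),
            method=method,
            fit_params=fit_params,
            occurrence_probability=p,
        )


def choose_distribution(force: ForceSeries, alpha: float = 0.05) -> str:
    """Pick the candidate law for a force series.

    Extreme-type measures always get the GEV. Aggregate measures are
    gated by the Shapiro–Wilk W-test at level ``alpha``: normal if the
    raw values pass, lognormal if only the log-transformed values pass.

    Raises
    ------
    ValueError
        If both the raw and log-transformed values fail the W-test, or
        if the lognormal fallback is needed but values are not all
        positive.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if force.measure_kind is MeasureKind.EXTREME:
        return "gev"
    _, p_raw = stats.shapiro(force.values)
    if p_raw >= alpha:
        return "normal"
    if np.any(force.values <= 0):
        raise ValueError(
            "normality rejected and lognormal fallback impossible: "
            "force series contains non-positive values"
        )
    _, p_log = stats.shapiro(np.log(force.values))
    if p_log >= alpha:
        return "lognormal"
    raise ValueError(
        "no admissible distribution: Shapiro-Wilk rejects normality of both "
        f"raw (p={p_raw:.3g}) and log-transformed (p={p_log:.3g}) values"
    )


def _tail_probability(dist, event_value: float, tail: Tail) -> float:
    return float(dist.sf(event_value) if tail is Tail.UPPER else dist.cdf(event_value))


def normal_return_period(
    force: ForceSeries,
    event_value: float,
    distribution: str = "normal",
    ddof: int = 1,
) -> IntensityEstimate:
    """Return period of ``event_value`` under a fitted normal/lognormal law.

    The mean and standard deviation are the sample statistics (``ddof=1``
    by default; ``ddof=0`` gives the strict MLE — the two differ only in
    the variance denominator and converge for long series). The
    occurrence probability is the tail probability of ``event_value`` in
    the harmful direction; the return period is its inverse.
    """
    if not np.isfinite(event_value):
        raise ValueError("event_value must be finite")
    x = force.values
    ev = float(event_value)
    if distribution == "lognormal":
        if np.any(x <= 0) or ev <= 0:
            raise ValueError("lognormal law requires positive values and event_value")
        x = np.log(x)
        ev = math.log(ev)
    elif distribution != "normal":
        raise ValueError(f"unknown distribution tag {distribution!r}")
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=ddof))
    if sd == 0.0:
        raise ValueError("degenerate force series: zero standard deviation")
    p = _tail_probability(stats.norm(mu, sd), ev, force.harmful_tail)
    return IntensityEstimate.from_probability(
        p, distribution, {"mean": mu, "sd": sd, "ddof": ddof}
    )


def gev_return_period(
    force: ForceSeries,
    event_value: float,
    params: dict | None = None,
) -> IntensityEstimate:
    """Return period of ``event_value`` under a GEV law for annual extremes.

    The GEV is fitted to the annual block values by maximum likelihood
    (block size is one year). Minima-type series (``harmful_tail ==
    'lower'``) are negated, fitted as maxima, and the exceedance taken on
    the negated scale — the standard block-minima device.

    Parameters
    ----------
    params
        Optional fixed parameters ``{'shape': xi, 'location': mu,
        'scale': sigma}`` on the observed data scale; when given, no
        fitting is performed and the tail probability is taken in the
        harmful direction directly. ``shape`` follows the convention in
        which xi > 0 is the heavy-tailed (Fréchet) domain.
    """
    if not np.isfinite(event_value):
        raise ValueError("event_value must be finite")
    if params is not None:
        c = -float(params["shape"])  # scipy's genextreme uses c = -xi
        dist = stats.genextreme(c, loc=params["location"], scale=params["scale"])
        p = _tail_probability(dist, float(event_value), force.harmful_tail)
        return IntensityEstimate.from_probability(p, "gev", dict(params) | {"fitted": False})

    if force.measure_kind is not MeasureKind.EXTREME:
        raise ValueError("GEV fitting expects an extreme-type measure")
    if len(force) < 10:
        warnings.warn(
            f"GEV fitted to only {len(force)} annual values; estimates may be unstable",
            stacklevel=2,
        )
    negated = force.harmful_tail is Tail.LOWER
    x = -force.values if negated else force.values
    ev = -float(event_value) if negated else float(event_value)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        c, loc, scale = stats.genextreme.fit(x)
    if not (np.isfinite([c, loc, scale]).all() and scale > 0):
        raise RuntimeError(
            f"GEV maximum-likelihood fit did not converge: c={c}, loc={loc}, scale={scale}"
        )
    p = float(stats.genextreme.sf(ev, c, loc=loc, scale=scale))
    return IntensityEstimate.from_probability(
        p,
        "gev",
        {"shape": -c, "location": loc, "scale": scale, "negated": negated, "fitted": True},
    )


def historical_return_period(rec: RareEventRecord) -> IntensityEstimate:
    """Return period from historical evidence: record length / event count."""
    if rec.n_events == 0:
        raise ValueError("return period undefined from zero events")
    rp = rec.record_length / rec.n_events
    return IntensityEstimate(
        return_period=rp,
        log10_return_period=math.log10(rp),
        method="historical",
        fit_params={"record_length": rec.record_length, "n_events": rec.n_events},
        occurrence_probability=rec.n_events / rec.record_length,
    )


def estimate_intensity(
    force: ForceSeries, event_value: float, alpha: float = 0.05
) -> IntensityEstimate:
    """Full intensity estimate: pick the law, fit it, invert the tail."""
    tag = choose_distribution(force, alpha=alpha)
    if tag == "gev":
        return gev_return_period(force, event_value)
    return normal_return_period(force, event_value, distribution=tag)
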