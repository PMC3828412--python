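"""Concentration descriptive statistics, lognormal fitting, and tail exceedance.

Indoor pollutant concentrations are well described by lognormal
distributions. When only printed group summaries (arithmetic mean and SD)
are available, the log-scale parameters are recovered by the method of
moments:

    sigma² = ln(1 + (sd/mean)²),    mu = ln(mean) − sigma²/2

which reproduces the input mean and SD exactly. The fraction of buildings
above a guideline threshold t is then the analytic upper tail
P(X > t) = 1 − Φ((ln t − mu)/sigma).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SampleSummary",
    "LognormalParams",
    "summarize",
    "fit_lognormal_mom",
    "fit_lognormal_mle",
    "exceedance_analytic",
    "exceedance_empirical",
]


@dataclass(frozen=True)
class SampleSummary:
    """Printed group statistics for one (building type, compound) stratum."""

    building_type: str
    compound: str
    n: int
    mean: float
    sd: float
    median: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.mean <= 0:
            raise ValueError(f"mean must be positive, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")
        if self.median is not None and self.median <= 0:
            raise ValueError(f"median must be positive, got {self.median}")


@dataclass(frozen=True)
class LognormalParams:
    """Log-scale location and spread of a fitted lognormal (log µg/m³)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not math.isfinite(self.arithmetic_mean):
            raise ValueError("implied arithmetic mean is not finite")

    @property
    def arithmetic_mean(self) -> float:
        return math.exp(self.mu + self.sigma**2 / 2)

    @property
    def arithmetic_sd(self) -> float:
        return self.arithmetic_mean * math.sqrt(math.expm1(self.sigma**2))

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    def frozen(self) -> stats.rv_continuous:
        """The scipy frozen distribution (s=sigma, scale=exp(mu))."""
        return stats.lognorm(s=self.sigma, scale=math.exp(self.mu))


def summarize(
    records: np.ndarray | list[float],
    building_type: str = "",
    compound: str = "",
) -> SampleSummary:
    """Arithmetic mean, sample SD (n−1 denominator) and median of raw records.

    Non-positive concentrations are physically impossible (and break the
    log transform), so they are rejected with the offending index.
    """
    values = np.asarray(records, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty record set")
    bad = np.flatnonzero(values <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive concentration at index {bad[0]}: {values[bad[0]]}"
        )
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return SampleSummary(
        building_type=building_type,
        compound=compound,
        n=int(values.size),
        mean=float(values.mean()),
        sd=sd,
        median=float(np.median(values)),
    )


def fit_lognormal_mom(
    mean: float, sd: float, printed_median: float | None = None
) -> LognormalParams:
    """Method-of-moments lognormal fit from an arithmetic mean and SD.

    The fitted distribution's arithmetic mean and SD equal the inputs to
    machine precision. If a printed median is supplied, the implied
    median exp(mu) is checked against it and a model-adequacy warning (not
    an error) is emitted when they disagree by more than 15%.
    """
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    params = LognormalParams(mu=math.log(mean) - sigma2 / 2, sigma=math.sqrt(sigma2))
    if printed_median is not None:
        implied = params.median
        if abs(implied - printed_median) > 0.15 * printed_median:
            warnings.warn(
                f"fitted lognormal median {implied:.1f} deviates >15% from the "
                f"reported median {printed_median:.1f}; the lognormal may fit "
                "this stratum poorly",
                stacklevel=2,
            )
    return params


def fit_lognormal_mle(records: np.ndarray | list[float]) -> LognormalParams:
    """Maximum-likelihood lognormal fit from raw concentration records.

    Offered for when raw data exist; the method-of-moments fit remains the
    default because published tables rarely carry more than mean and SD.
    """
    values = np.asarray(records, dtype=float)
    if values.size < 2:
        raise ValueError("MLE fit needs at least 2 records")
    if np.any(values <= 0):
        raise ValueError("non-positive concentrations cannot be log-transformed")
    logs = np.log(values)
    return LognormalParams(mu=float(logs.mean()), sigma=float(logs.std(ddof=0)))


def exceedance_analytic(params: LognormalParams, threshold: float) -> float:
    """P(X > threshold) under the fitted lognormal, as a fraction in [0, 1]."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return float(stats.norm.sf((math.log(threshold) - params.mu) / params.sigma))


def exceedance_empirical(records: np.ndarray | list[float], threshold: float) -> float:
    """Fraction of records strictly above the threshold; ties count as compliant."""
    values = np.asarray(records, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute exceedance of an empty record set")
    return float(np.mean(values > threshold))
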