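"""Synthetic biomonitoring cohorts for the nickel–thyroid analysis.

Emulates the statistical structure the pipeline assumes: right-skewed
(log-normal) blood-nickel distributions per sex, hormone panels whose
marginal quartiles match configurable targets, per-endpoint missingness, and
an optional quantal dose-response link tying the probability that a hormone
falls outside its reference range to the nickel level.

Distributions are parameterized by printed cohort quartiles: a log-normal by
(median, p75/p25 ratio) — a two-parameter family cannot honour three
arbitrary quartiles, so the median and the quartile ratio are the calibration
contract — and a normal by (median, IQR).  Hormones are truncated at zero.

When a link is configured for a measured hormone, the subject's in/out-of-
range indicator is drawn first from the quantal model of the nickel dose and
the continuous hormone value is then drawn from the marginal distribution
truncated to the corresponding region, keeping the continuous panel and the
quantal table mutually consistent.  The SPINA endpoints are computed from the
hormone draws, so hormone-level links induce an indirect dose dependence in
SPINA-GT/GD.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import HORMONES, REFERENCE_RANGES
from .families import get_family

__all__ = [
    "LognormalSpec",
    "NormalSpec",
    "DoseSpec",
    "LinkSpec",
    "SyntheticConfig",
    "generate_cohort",
    "generate_quantal",
]

_Z75 = 0.6744897501960817  # standard normal 75th percentile


@dataclass(frozen=True)
class LognormalSpec:
    """Log-normal marginal fixed by its median and p75/p25 ratio."""

    median: float
    p25: float
    p75: float

    def __post_init__(self) -> None:
        if not 0 < self.p25 < self.median < self.p75:
            raise ValueError(
                f"quartile targets must satisfy 0 < p25 < median < p75, got "
                f"({self.p25}, {self.median}, {self.p75})"
            )

    @property
    def mu(self) -> float:
        return float(np.log(self.median))

    @property
    def sigma(self) -> float:
        return float(np.log(self.p75 / self.p25) / (2.0 * _Z75))

    def frozen(self):
        return stats.lognorm(s=self.sigma, scale=np.exp(self.mu))


@dataclass(frozen=True)
class NormalSpec:
    """Normal marginal fixed by its median and interquartile range,
    truncated at zero (concentrations cannot be negative)."""

    median: float
    p25: float
    p75: float

    def __post_init__(self) -> None:
        if not self.p25 < self.median < self.p75:
            raise ValueError(
                f"quartile targets must satisfy p25 < median < p75, got "
                f"({self.p25}, {self.median}, {self.p75})"
            )

    @property
    def sigma(self) -> float:
        return float((self.p75 - self.p25) / (2.0 * _Z75))

    def frozen(self):
        a = (0.0 - self.median) / self.sigma
        return stats.truncnorm(a=a, b=np.inf, loc=self.median, scale=self.sigma)


@dataclass(frozen=True)
class DoseSpec:
    """Dose distribution for simulated quantal datasets.

    ``kind`` is ``"log_uniform"`` (uniform in log dose between ``low`` and
    ``high``) or ``"log_normal"`` (median ``median``, log-sd ``sigma``).
    """

    kind: str = "log_normal"
    low: float = 0.1
    high: float = 100.0
    median: float = 8.0
    sigma: float = 1.2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "log_uniform":
            return np.exp(rng.uniform(np.log(self.low), np.log(self.high), size=n))
        if self.kind == "log_normal":
            return np.exp(rng.normal(np.log(self.median), self.sigma, size=n))
        raise ValueError(f"unknown dose spec kind {self.kind!r}")


@dataclass(frozen=True)
class LinkSpec:
    """Quantal dose-response link between nickel and one hormone endpoint.

    The out-of-range probability follows the configured family with
    background ``background`` and true BMD (at extra risk ``bmr``) equal to
    ``bmd``, with log-dose steepness ``sigma`` for the log-dose families.
    """

    endpoint: str
    family: str = "log_logistic"
    background: float = 0.05
    bmd: float = 5.0
    bmr: float = 0.10
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.endpoint not in HORMONES:
            raise ValueError(
                f"links are supported on measured hormone endpoints {HORMONES}, "
                f"got {self.endpoint!r}"
            )
        if not 0.0 <= self.background < 1.0:
            raise ValueError("background must lie in [0, 1)")
        if not self.bmd > 0:
            raise ValueError("true BMD must be > 0")
        if not 0.0 < self.bmr < 1.0:
            raise ValueError("bmr must lie in (0, 1)")

    @property
    def params(self) -> np.ndarray:
        fam = get_family(self.family)
        if self.family == "log_logistic":
            from scipy.special import logit

            mu = np.log(self.bmd) - self.sigma * logit(self.bmr)
            return np.array([self.background, mu, self.sigma])
        if self.family == "log_probit":
            from scipy.special import ndtri

            mu = np.log(self.bmd) - self.sigma * ndtri(self.bmr)
            return np.array([self.background, mu, self.sigma])
        if self.family == "weibull":
            c = 1.0 / self.sigma
            ln_b = np.log(self.bmd) - np.log(-np.log1p(-self.bmr)) / c
            return np.array([self.background, ln_b, c])
        raise ValueError(
            f"link family {self.family!r} not supported; use log_logistic, "
            "log_probit or weibull"
        )

    def prob(self, dose) -> np.ndarray:
        return get_family(self.family).prob(self.params, dose)


def _default_ni() -> dict[str, LognormalSpec]:
    return {
        "M": LognormalSpec(median=8.278, p25=2.902, p75=14.20),
        "F": LognormalSpec(median=7.609, p25=1.771, p75=15.70),
    }


def _default_hormones() -> dict[str, dict[str, object]]:
    # TSH is right-skewed -> log-normal; the iodothyronines are roughly
    # symmetric -> truncated normal.  Targets: observed cohort quartiles.
    return {
        "M": {
            "tsh": LognormalSpec(median=1.870, p25=1.020, p75=2.700),
            "ft4": NormalSpec(median=16.84, p25=15.37, p75=19.09),
            "ft3": NormalSpec(median=4.760, p25=4.295, p75=5.290),
            "t4": NormalSpec(median=116.5, p25=101.4, p75=132.8),
            "t3": NormalSpec(median=1.950, p25=1.630, p75=2.180),
        },
        "F": {
            "tsh": LognormalSpec(median=1.790, p25=1.105, p75=2.530),
            "ft4": NormalSpec(median=15.63, p25=5.718, p75=18.46),
            "ft3": NormalSpec(median=4.910, p25=4.173, p75=5.623),
            "t4": NormalSpec(median=109.7, p25=94.66, p75=125.0),
            "t3": NormalSpec(median=1.955, p25=1.658, p75=2.203),
        },
    }


def _default_missingness() -> dict[str, dict[str, float]]:
    # Per-endpoint missing fractions implied by in+out row totals versus the
    # stratum sizes (217 men, 218 women).
    return {
        "M": {"tsh": 24 / 217, "ft4": 32 / 217, "ft3": 29 / 217,
              "t4": 21 / 217, "t3": 23 / 217},
        "F": {"tsh": 15 / 218, "ft4": 10 / 218, "ft3": 14 / 218,
              "t4": 12 / 218, "t3": 17 / 218},
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic cohort generator.

    Defaults reproduce the study conditions: 217 men and 218 women aged
    18–94, per-sex log-normal nickel marginals and hormone marginals matched
    to the cohort quartiles, per-endpoint missingness implied by the
    in/out-of-range row totals, and no dose-response link (hormones
    independent of nickel) unless ``links`` is set.
    """

    n_male: int = 217
    n_female: int = 218
    age_range: tuple[int, int] = (18, 94)
    frac_healthy: float = 136 / 435
    ni: Mapping[str, LognormalSpec] = field(default_factory=_default_ni)
    hormones: Mapping[str, Mapping[str, object]] = field(
        default_factory=_default_hormones
    )
    missingness: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_missingness
    )
    links: Sequence[LinkSpec] = ()

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0 or self.n_male + self.n_female < 1:
            raise ValueError("cohort size must be at least 1")
        for sex, rates in self.missingness.items():
            for endpoint, rate in rates.items():
                if not 0.0 <= rate < 1.0:
                    raise ValueError(
                        f"missingness for {sex}/{endpoint} must lie in [0, 1), "
                        f"got {rate}"
                    )

    def link_for(self, endpoint: str) -> Optional[LinkSpec]:
        for link in self.links:
            if link.endpoint == endpoint:
                return link
        return None


def _sample_region(
    dist, low: float, high: float, inside: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw from ``dist`` conditioned inside/outside [low, high] elementwise.

    Uses the probability-integral transform: a uniform draw is mapped into
    the CDF mass of the requested region, tails weighted by their mass.
    """
    n = inside.size
    f_lo = float(dist.cdf(low))
    f_hi = float(dist.cdf(high))
    u = np.empty(n)

    u_raw = rng.random(n)
    # inside: uniform on (F(lo), F(hi))
    mass_in = max(f_hi - f_lo, 1e-12)
    u[inside] = f_lo + u_raw[inside] * mass_in
    # outside: pick a tail proportionally to its mass
    out = ~inside
    if out.any():
        mass_low = max(f_lo, 1e-12)
        mass_high = max(1.0 - f_hi, 1e-12)
        pick_low = rng.random(n)[out] < mass_low / (mass_low + mass_high)
        u_out = np.where(
            pick_low,
            u_raw[out] * mass_low,
            f_hi + u_raw[out] * mass_high,
        )
        u[out] = u_out
    return dist.ppf(np.clip(u, 1e-12, 1.0 - 1e-12))


def generate_cohort(
    config: SyntheticConfig = SyntheticConfig(), seed: Optional[int] = None
) -> pd.DataFrame:
    """Generate a synthetic cohort frame.

    Columns: ``id, sex, age, group, ni, tsh, ft4, ft3, t4, t3`` with NaN for
    missing hormone determinations.  Reproducible: the same (config, seed)
    pair always yields the identical frame.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    frames = []
    for sex, n in (("M", config.n_male), ("F", config.n_female)):
        if n == 0:
            continue
        ni = config.ni[sex].frozen().rvs(size=n, random_state=rng)
        age_lo, age_hi = config.age_range
        age = np.clip(
            np.round(rng.normal(50.0, 15.0, size=n)), age_lo, age_hi
        ).astype(int)
        healthy = rng.random(n) < config.frac_healthy
        data = {
            "sex": np.repeat(sex, n),
            "age": age,
            "group": np.where(healthy, "healthy", "unhealthy"),
            "ni": ni,
        }
        for endpoint in HORMONES:
            spec = config.hormones[sex][endpoint]
            dist = spec.frozen()
            link = config.link_for(endpoint)
            if link is None:
                values = dist.rvs(size=n, random_state=rng)
            else:
                low, high = REFERENCE_RANGES[endpoint]
                p_out = np.clip(link.prob(ni), 0.0, 1.0)
                inside = rng.random(n) >= p_out
                values = _sample_region(dist, low, high, inside, rng)
            rate = config.missingness.get(sex, {}).get(endpoint, 0.0)
            if rate > 0:
                values = np.where(rng.random(n) < rate, np.nan, values)
            data[endpoint] = values
        frames.append(pd.DataFrame(data))
    cohort = pd.concat(frames, ignore_index=True)
    cohort.insert(0, "id", [f"S{i:04d}" for i in range(len(cohort))])
    return cohort


def generate_quantal(
    n: int,
    dose_spec: DoseSpec = DoseSpec(),
    family: str = "log_logistic",
    params=None,
    link: Optional[LinkSpec] = None,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (doses, 0/1 outcomes) from a known quantal dose-response.

    Either pass explicit family ``params`` or a :class:`LinkSpec` (whose
    closed-form true BMD makes recovery tests possible).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    doses = dose_spec.sample(n, rng)
    if link is not None:
        p = link.prob(doses)
    else:
        if params is None:
            raise ValueError("provide either params or a LinkSpec")
        p = get_family(family).prob(np.asarray(params, dtype=float), doses)
    outcomes = (rng.random(n) < np.clip(p, 0.0, 1.0)).astype(float)
    return doses, outcomes
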