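"""Quantal dose-response model families.

The classical suite used for quantal benchmark-dose model averaging:
logistic, probit, log-logistic, log-probit, Weibull, gamma and two-stage.
Each family exposes its response probability P(d), the background response
P0 = lim_{d->0+} P(d), parameter bounds tied to the observed dose range (which
makes every fitted family equivariant under a rescaling of the dose axis), a
heuristic starting point, and — where available — the closed-form benchmark
dose at extra risk BMR:

    extra risk:  P(BMD) = P0 + BMR * (1 - P0)

Parameter conventions (all finite; `a` is the background probability):

=============  =======================  =====================================
family         parameters               response P(d)
=============  =======================  =====================================
logistic       alpha, beta >= 0         1 / (1 + exp(-(alpha + beta*d)))
probit         alpha, beta >= 0         Phi(alpha + beta*d)
log_logistic   a, mu, sigma > 0         a + (1-a) / (1 + exp(-(ln d - mu)/sigma))
log_probit     a, mu, sigma > 0         a + (1-a) * Phi((ln d - mu)/sigma)
weibull        a, ln_b, c > 0           a + (1-a) * (1 - exp(-(d/b)^c))
gamma          a, ln_b, c > 0           a + (1-a) * GammaReg(c, d/b)
two_stage      a, b >= 0, c >= 0        a + (1-a) * (1 - exp(-(b*d + c*d^2)))
=============  =======================  =====================================

Shape parameters (Weibull/gamma ``c`` and the log-dose ``sigma``) carry a
positive lower bound of 1e-2: unconstrained shapes can make the extra-risk
inversion ill-posed at low doses.  Linear-dose slopes (logistic/probit
``beta``, two-stage ``b``/``c``) are allowed to reach 0 so that every family
can collapse exactly to a dose-independent response.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import special

__all__ = ["QuantalFamily", "FAMILIES", "DEFAULT_SUITE", "get_family"]

_A_MAX = 1.0 - 1e-6
_SHAPE_MIN = 1e-2
_SHAPE_MAX = 18.0
_EXP_CLIP = 700.0


def _expit(x):
    return special.expit(x)


def _phi(x):
    return special.ndtr(x)


class QuantalFamily:
    """Base class; subclasses implement one parametric dose-response family."""

    name: str = ""
    param_names: tuple[str, ...] = ()
    #: whether P(d) requires d > 0 (log-dose families)
    log_dose: bool = False

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # -- interface -----------------------------------------------------
    def prob(self, params: np.ndarray, dose) -> np.ndarray:
        """Response probability at ``dose`` (array-aware)."""
        raise NotImplementedError

    def background(self, params: np.ndarray) -> float:
        """P0 = lim_{d->0+} P(d)."""
        raise NotImplementedError

    def bounds(self, doses: np.ndarray) -> list[tuple[float, float]]:
        """Box constraints for the parameters, scaled to the dose range."""
        raise NotImplementedError

    def heuristic_params(self, doses: np.ndarray, outcomes: np.ndarray) -> np.ndarray:
        """A data-driven starting point inside the bounds."""
        raise NotImplementedError

    def bmd_extra(self, params: np.ndarray, bmr: float) -> Optional[float]:
        """Closed-form BMD at extra risk ``bmr``; None when unavailable,
        inf when the response never reaches the benchmark level."""
        return None

    def prob_grad(
        self, params: np.ndarray, dose, ln_dose: Optional[np.ndarray] = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Response P(d) and its parameter Jacobian, shape (n, n_params).

        Assumes in-domain doses (the fitting loop validates once up front);
        ``ln_dose`` may carry precomputed log-doses for the log-dose families.
        """
        raise NotImplementedError

    # -- helpers -------------------------------------------------------
    def _check_dose(self, dose) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        if self.log_dose and np.any(d <= 0):
            raise ValueError(f"{self.name}: dose must be > 0 for log-dose families")
        if np.any(d < 0):
            raise ValueError(f"{self.name}: dose must be non-negative")
        return d

    @staticmethod
    def _rate_low(doses: np.ndarray, outcomes: np.ndarray) -> float:
        """Observed response rate in the lowest-dose third, clipped away from 0/1."""
        order = np.argsort(doses)
        k = max(len(doses) // 3, 1)
        rate = float(np.mean(outcomes[order[:k]]))
        return float(np.clip(rate, 0.01, 0.8))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<QuantalFamily {self.name}>"


class Logistic(QuantalFamily):
    name = "logistic"
    param_names = ("alpha", "beta")

    def prob(self, params, dose):
        alpha, beta = params
        d = np.asarray(dose, dtype=float)
        return _expit(alpha + beta * d)

    def background(self, params):
        return float(_expit(params[0]))

    def bounds(self, doses):
        dmax = float(np.max(doses))
        return [(-30.0, 30.0), (0.0, 1e3 / dmax)]

    def heuristic_params(self, doses, outcomes):
        p0 = self._rate_low(doses, outcomes)
        return np.array([special.logit(p0), 1.0 / np.median(doses)])

    def bmd_extra(self, params, bmr):
        alpha, beta = params
        if beta <= 0:
            return np.inf
        p0 = _expit(alpha)
        target = p0 + bmr * (1.0 - p0)
        return float((special.logit(target) - alpha) / beta)

    def prob_grad(self, params, dose, ln_dose=None):
        alpha, beta = params
        d = np.asarray(dose, dtype=float)
        p = _expit(alpha + beta * d)
        dp = p * (1.0 - p)
        return p, np.column_stack([dp, dp * d])


class Probit(QuantalFamily):
    name = "probit"
    param_names = ("alpha", "beta")

    def prob(self, params, dose):
        alpha, beta = params
        d = self._check_dose(dose)
        return _phi(alpha + beta * d)

    def background(self, params):
        return float(_phi(params[0]))

    def bounds(self, doses):
        dmax = float(np.max(doses))
        return [(-8.0, 8.0), (0.0, 1e2 / dmax)]

    def heuristic_params(self, doses, outcomes):
        p0 = self._rate_low(doses, outcomes)
        return np.array([special.ndtri(p0), 1.0 / np.median(doses)])

    def bmd_extra(self, params, bmr):
        alpha, beta = params
        if beta <= 0:
            return np.inf
        p0 = _phi(alpha)
        target = p0 + bmr * (1.0 - p0)
        return float((special.ndtri(target) - alpha) / beta)

    def prob_grad(self, params, dose, ln_dose=None):
        alpha, beta = params
        d = np.asarray(dose, dtype=float)
        eta = alpha + beta * d
        p = _phi(eta)
        dp = np.exp(-0.5 * eta * eta) / np.sqrt(2.0 * np.pi)
        return p, np.column_stack([dp, dp * d])


class LogLogistic(QuantalFamily):
    name = "log_logistic"
    param_names = ("a", "mu", "sigma")
    log_dose = True

    def prob(self, params, dose):
        a, mu, sigma = params
        d = self._check_dose(dose)
        return a + (1.0 - a) * _expit((np.log(d) - mu) / sigma)

    def background(self, params):
        return float(params[0])

    def bounds(self, doses):
        lo, hi = np.log(np.min(doses)), np.log(np.max(doses))
        return [(0.0, _A_MAX), (lo - 7.0, hi + 7.0), (_SHAPE_MIN, _SHAPE_MAX)]

    def heuristic_params(self, doses, outcomes):
        p0 = min(self._rate_low(doses, outcomes), 0.5)
        return np.array([p0, float(np.median(np.log(doses))), 1.0])

    def bmd_extra(self, params, bmr):
        _, mu, sigma = params
        return float(np.exp(mu + sigma * special.logit(bmr)))

    def prob_grad(self, params, dose, ln_dose=None):
        a, mu, sigma = params
        ld = np.log(np.asarray(dose, dtype=float)) if ln_dose is None else ln_dose
        z = (ld - mu) / sigma
        f = _expit(z)
        df = f * (1.0 - f)
        return (
            a + (1.0 - a) * f,
            np.column_stack([
                1.0 - f,
                (1.0 - a) * df * (-1.0 / sigma),
                (1.0 - a) * df * (-z / sigma),
            ]),
        )


class LogProbit(QuantalFamily):
    name = "log_probit"
    param_names = ("a", "mu", "sigma")
    log_dose = True

    def prob(self, params, dose):
        a, mu, sigma = params
        d = self._check_dose(dose)
        return a + (1.0 - a) * _phi((np.log(d) - mu) / sigma)

    def background(self, params):
        return float(params[0])

    def bounds(self, doses):
        lo, hi = np.log(np.min(doses)), np.log(np.max(doses))
        return [(0.0, _A_MAX), (lo - 7.0, hi + 7.0), (_SHAPE_MIN, _SHAPE_MAX)]

    def heuristic_params(self, doses, outcomes):
        p0 = min(self._rate_low(doses, outcomes), 0.5)
        return np.array([p0, float(np.median(np.log(doses))), 1.0])

    def bmd_extra(self, params, bmr):
        _, mu, sigma = params
        return float(np.exp(mu + sigma * special.ndtri(bmr)))

    def prob_grad(self, params, dose, ln_dose=None):
        a, mu, sigma = params
        ld = np.log(np.asarray(dose, dtype=float)) if ln_dose is None else ln_dose
        z = (ld - mu) / sigma
        f = _phi(z)
        df = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
        return (
            a + (1.0 - a) * f,
            np.column_stack([
                1.0 - f,
                (1.0 - a) * df * (-1.0 / sigma),
                (1.0 - a) * df * (-z / sigma),
            ]),
        )


class Weibull(QuantalFamily):
    name = "weibull"
    param_names = ("a", "ln_b", "c")
    log_dose = True

    def prob(self, params, dose):
        a, ln_b, c = params
        d = self._check_dose(dose)
        x = np.exp(np.clip(c * (np.log(d) - ln_b), -_EXP_CLIP, _EXP_CLIP))
        return a + (1.0 - a) * (-np.expm1(-x))

    def background(self, params):
        return float(params[0])

    def bounds(self, doses):
        lo, hi = np.log(np.min(doses)), np.log(np.max(doses))
        return [(0.0, _A_MAX), (lo - 7.0, hi + 7.0), (_SHAPE_MIN, _SHAPE_MAX)]

    def heuristic_params(self, doses, outcomes):
        p0 = min(self._rate_low(doses, outcomes), 0.5)
        return np.array([p0, float(np.median(np.log(doses))), 1.0])

    def bmd_extra(self, params, bmr):
        _, ln_b, c = params
        return float(np.exp(ln_b + np.log(-np.log1p(-bmr)) / c))

    def prob_grad(self, params, dose, ln_dose=None):
        a, ln_b, c = params
        ld = np.log(np.asarray(dose, dtype=float)) if ln_dose is None else ln_dose
        u = ld - ln_b
        x = np.exp(np.clip(c * u, -_EXP_CLIP, _EXP_CLIP))
        ex = np.exp(-x)
        f = -np.expm1(-x)
        return (
            a + (1.0 - a) * f,
            np.column_stack([
                1.0 - f,
                (1.0 - a) * ex * (-c * x),
                (1.0 - a) * ex * x * u,
            ]),
        )


class Gamma(QuantalFamily):
    name = "gamma"
    param_names = ("a", "ln_b", "c")
    log_dose = True

    def prob(self, params, dose):
        a, ln_b, c = params
        d = self._check_dose(dose)
        return a + (1.0 - a) * special.gammainc(c, d / np.exp(ln_b))

    def background(self, params):
        return float(params[0])

    def bounds(self, doses):
        lo, hi = np.log(np.min(doses)), np.log(np.max(doses))
        return [(0.0, _A_MAX), (lo - 9.0, hi + 9.0), (_SHAPE_MIN, _SHAPE_MAX)]

    def heuristic_params(self, doses, outcomes):
        p0 = min(self._rate_low(doses, outcomes), 0.5)
        return np.array([p0, float(np.median(np.log(doses))), 1.0])

    def bmd_extra(self, params, bmr):
        _, ln_b, c = params
        return float(np.exp(ln_b) * special.gammaincinv(c, bmr))

    def prob_grad(self, params, dose, ln_dose=None):
        a, ln_b, c = params
        d = np.asarray(dose, dtype=float)
        ld = np.log(d) if ln_dose is None else ln_dose
        s = d * np.exp(-ln_b)
        f = special.gammainc(c, s)
        # dF/ds = s^(c-1) e^(-s) / Gamma(c); ds/dln_b = -s
        with np.errstate(over="ignore", under="ignore"):
            dens = np.exp((c - 1.0) * (ld - ln_b) - s - special.gammaln(c))
        # shape derivative has no elementary closed form: central difference
        h = 1e-6 * max(c, 1.0)
        c_lo = max(c - h, 1e-8)
        df_dc = (special.gammainc(c + h, s) - special.gammainc(c_lo, s)) / (c + h - c_lo)
        return (
            a + (1.0 - a) * f,
            np.column_stack([
                1.0 - f,
                (1.0 - a) * (-s * dens),
                (1.0 - a) * df_dc,
            ]),
        )


class TwoStage(QuantalFamily):
    name = "two_stage"
    param_names = ("a", "b", "c")

    def prob(self, params, dose):
        a, b, c = params
        d = self._check_dose(dose)
        x = np.clip(b * d + c * d * d, 0.0, _EXP_CLIP)
        return a + (1.0 - a) * (-np.expm1(-x))

    def background(self, params):
        return float(params[0])

    def bounds(self, doses):
        dmax = float(np.max(doses))
        return [(0.0, _A_MAX), (0.0, 50.0 / dmax), (0.0, 50.0 / dmax**2)]

    def heuristic_params(self, doses, outcomes):
        p0 = min(self._rate_low(doses, outcomes), 0.5)
        dmed = float(np.median(doses))
        return np.array([p0, 0.1 / dmed, 0.0])

    def bmd_extra(self, params, bmr):
        _, b, c = params
        target = -np.log1p(-bmr)  # b*d + c*d^2 = target
        if b <= 0 and c <= 0:
            return np.inf
        if c <= 0:
            return float(target / b)
        return float((-b + np.sqrt(b * b + 4.0 * c * target)) / (2.0 * c))

    def prob_grad(self, params, dose, ln_dose=None):
        a, b, c = params
        d = np.asarray(dose, dtype=float)
        x = np.clip(b * d + c * d * d, 0.0, _EXP_CLIP)
        ex = np.exp(-x)
        f = -np.expm1(-x)
        return (
            a + (1.0 - a) * f,
            np.column_stack([
                1.0 - f,
                (1.0 - a) * ex * d,
                (1.0 - a) * ex * d * d,
            ]),
        )


class Background(QuantalFamily):
    """Dose-independent null model P(d) = a; the nesting baseline for every
    family in the suite and the reference point of likelihood sanity checks."""

    name = "background"
    param_names = ("a",)

    def prob(self, params, dose):
        (a,) = params
        d = self._check_dose(dose)
        return np.full(d.shape, float(a))

    def background(self, params):
        return float(params[0])

    def bounds(self, doses):
        return [(0.0, _A_MAX)]

    def heuristic_params(self, doses, outcomes):
        return np.array([float(np.clip(np.mean(outcomes), 0.01, 0.99))])

    def bmd_extra(self, params, bmr):
        return np.inf  # a flat response never reaches the benchmark level

    def prob_grad(self, params, dose, ln_dose=None):
        (a,) = params
        d = np.asarray(dose, dtype=float)
        return np.full(d.shape, float(a)), np.ones((d.size, 1))


FAMILIES: dict[str, QuantalFamily] = {
    fam.name: fam
    for fam in (
        Logistic(),
        Probit(),
        LogLogistic(),
        LogProbit(),
        Weibull(),
        Gamma(),
        TwoStage(),
        Background(),
    )
}

#: The default model-averaging suite, in canonical order.
DEFAULT_SUITE: tuple[str, ...] = (
    "logistic",
    "probit",
    "log_logistic",
    "log_probit",
    "weibull",
    "gamma",
    "two_stage",
)


def get_family(family) -> QuantalFamily:
    """Resolve a family name or instance to a :class:`QuantalFamily`."""
    if isinstance(family, QuantalFamily):
        return family
    try:
        return FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown quantal family {family!r}; available: {sorted(FAMILIES)}"
        ) from None


def model_probability(family, params: Sequence[float], dose):
    """Evaluate the response probability of ``family`` at ``dose``.

    Thin functional wrapper over :meth:`QuantalFamily.prob` with parameter
    validation against the family's structural constraints.
    """
    fam = get_family(family)
    params = np.asarray(params, dtype=float)
    if params.shape != (fam.n_params,):
        raise ValueError(
            f"{fam.name} expects {fam.n_params} parameters {fam.param_names}, "
            f"got {params.shape}"
        )
    _validate_params(fam, params)
    return fam.prob(params, dose)


def _validate_params(fam: QuantalFamily, params: np.ndarray) -> None:
    if not np.all(np.isfinite(params)):
        raise ValueError(f"{fam.name}: parameters must be finite")
    named = dict(zip(fam.param_names, params))
    if "a" in named and not (0.0 <= named["a"] <= 1.0):
        raise ValueError(f"{fam.name}: background a must lie in [0, 1]")
    for key in ("beta", "b", "c"):
        if key in named and named[key] < 0:
            raise ValueError(f"{fam.name}: parameter {key} must be >= 0")
    if "sigma" in named and named["sigma"] <= 0:
        raise ValueError(f"{fam.name}: sigma must be > 0")
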