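"""Model-averaged quantal benchmark-dose estimation with bootstrap limits.

Workflow: fit a suite of quantal dose-response families to individual-level
(dose, 0/1) data by maximum Bernoulli likelihood, weight them by Akaike
weights, invert the model-averaged curve at a benchmark response (default:
10% extra risk) to obtain the BMD point estimate, and obtain BMDL/BMDU as the
5th/95th percentiles of a parametric bootstrap (outcomes redrawn from the
fitted model-averaged probabilities at the observed doses, full suite refit
per iteration).  The BMDL–BMDU interval ("BMDI") is conventionally called
narrow when BMDU/BMDL < 10.

The engine is exposed both as the sklearn-style estimator
:class:`QuantalBMD` and as the functional wrapper :func:`model_average_bmd`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from .families import DEFAULT_SUITE, get_family

__all__ = [
    "QuantalModelFit",
    "ModelSuiteFit",
    "BMDResult",
    "fit_model",
    "fit_suite",
    "akaike_weights",
    "bmd_from_curve",
    "model_average_bmd",
    "bmdi_ratio",
    "bootstrap_curve_export",
    "QuantalBMD",
]

_P_EPS = 1e-12
_NARROW_RATIO = 10.0  # BMDU/BMDL below this flags a "narrow" interval


# ---------------------------------------------------------------------------
# single-model maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class QuantalModelFit:
    """One fitted quantal dose-response model."""

    family: str
    params: np.ndarray
    loglik: float
    aic: float
    converged: bool
    degenerate: bool
    n: int
    k: int

    def predict(self, dose) -> np.ndarray:
        """Fitted response probability P(d)."""
        if self.degenerate:
            d = np.asarray(dose, dtype=float)
            return np.full(d.shape, float(self.params[0]))
        return get_family(self.family).prob(self.params, dose)

    def background(self) -> float:
        if self.degenerate:
            return float(self.params[0])
        return get_family(self.family).background(self.params)


def _degenerate_fit(family_name: str, y: np.ndarray) -> QuantalModelFit:
    """Background-only collapse used when the outcomes are all 0 or all 1."""
    p_hat = float(np.mean(y))
    k = float(y.sum())
    n = float(y.size)
    # analytic null likelihood with the 0*log(0) = 0 convention
    ll = (k * np.log(p_hat) if k else 0.0) + (
        (n - k) * np.log(1.0 - p_hat) if n - k else 0.0
    )
    return QuantalModelFit(
        family=family_name,
        params=np.array([p_hat]),
        loglik=ll,
        aic=2.0 * 1 - 2.0 * ll,
        converged=True,
        degenerate=True,
        n=int(y.size),
        k=1,
    )


def fit_model(
    doses,
    outcomes,
    family,
    n_starts: int = 10,
    random_state=None,
    warm_start: Optional[np.ndarray] = None,
    ftol: float = 1e-13,
) -> QuantalModelFit:
    """Maximum-likelihood fit of one family to individual quantal data.

    Optimizes the Bernoulli log-likelihood over the family's box constraints
    with multi-start L-BFGS-B (Latin-hypercube starts in the unit box plus a
    data-driven heuristic start and, optionally, a warm start).  The
    ``converged`` flag reports whether any start terminated successfully;
    the best likelihood is kept either way.

    Parameters
    ----------
    doses, outcomes : array-like
        Strictly positive doses and 0/1 outcomes, one entry per subject.
    family : str or QuantalFamily
        Which dose-response family to fit.
    n_starts : int
        Number of Latin-hypercube starts (>= 1).
    random_state : int, numpy Generator or SeedSequence, optional
        Seeds the start draws; fits are deterministic given it.
    warm_start : ndarray, optional
        A parameter vector used as an additional start (e.g. the fit to the
        original data when refitting bootstrap resamples).
    """
    fam = get_family(family)
    d = np.asarray(doses, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("doses and outcomes must be 1-d arrays of equal length")
    if d.size == 0:
        raise ValueError("empty data")
    if np.any(d <= 0):
        raise ValueError("doses must be strictly positive")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcomes must be 0/1")

    if y.min() == y.max():
        return _degenerate_fit(fam.name, y)

    bounds = np.asarray(fam.bounds(d), dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo

    ln_d = np.log(d) if fam.log_dose else None
    idx1 = np.flatnonzero(y == 1.0)
    idx0 = np.flatnonzero(y == 0.0)

    def neg_loglik_and_grad(z: np.ndarray) -> tuple[float, np.ndarray]:
        p, grad_p = fam.prob_grad(lo + span * z, d, ln_dose=ln_d)
        pc = np.clip(p, _P_EPS, 1.0 - _P_EPS)
        f = -float(np.log(pc[idx1]).sum() + np.log1p(-pc[idx0]).sum())
        w = np.empty_like(pc)
        w[idx1] = -1.0 / pc[idx1]
        w[idx0] = 1.0 / (1.0 - pc[idx0])
        return f, (w @ grad_p) * span

    starts = []
    heuristic = np.clip((fam.heuristic_params(d, y) - lo) / span, 0.0, 1.0)
    starts.append(heuristic)
    if warm_start is not None and len(warm_start) == fam.n_params:
        starts.append(np.clip((np.asarray(warm_start, float) - lo) / span, 0.0, 1.0))
    if n_starts > 0:
        rng = np.random.default_rng(random_state)
        sampler = qmc.LatinHypercube(d=fam.n_params, seed=rng)
        starts.extend(sampler.random(n=n_starts))

    best_fun = np.inf
    best_z = starts[0]
    any_success = False
    z_bounds = [(0.0, 1.0)] * fam.n_params
    for z0 in starts:
        res = optimize.minimize(
            neg_loglik_and_grad,
            np.asarray(z0, dtype=float),
            method="L-BFGS-B",
            jac=True,
            bounds=z_bounds,
            options={"ftol": ftol, "gtol": 1e-9, "maxiter": 400},
        )
        any_success = any_success or bool(res.success)
        if res.fun < best_fun:
            best_fun = res.fun
            best_z = res.x

    params = lo + span * best_z
    ll = -best_fun
    return QuantalModelFit(
        family=fam.name,
        params=params,
        loglik=ll,
        aic=2.0 * fam.n_params - 2.0 * ll,
        converged=any_success,
        degenerate=False,
        n=int(y.size),
        k=fam.n_params,
    )


# ---------------------------------------------------------------------------
# suite fitting and Akaike weights
# ---------------------------------------------------------------------------

@dataclass
class ModelSuiteFit:
    """A weighted suite of fitted models (weights from Akaike's criterion)."""

    fits: list[QuantalModelFit]
    weights: np.ndarray

    def curve(self) -> Callable[[np.ndarray], np.ndarray]:
        """The model-averaged response P(d) = sum_k w_k P_k(d)."""
        usable = [(w, f) for w, f in zip(self.weights, self.fits) if w > 0]

        def ma(dose):
            d = np.asarray(dose, dtype=float)
            out = np.zeros(d.shape)
            for w, f in usable:
                out += w * f.predict(d)
            return out

        return ma

    def background(self) -> float:
        return float(
            sum(w * f.background() for w, f in zip(self.weights, self.fits) if w > 0)
        )


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights w_k = exp(-dAIC_k/2) / sum_j exp(-dAIC_j/2).

    Non-finite AIC entries (non-converged models) receive weight 0; at least
    one finite AIC is required.
    """
    aics = np.asarray(aics, dtype=float)
    finite = np.isfinite(aics)
    if not finite.any():
        raise ValueError("akaike_weights requires at least one finite AIC")
    w = np.zeros(aics.shape)
    rel = aics[finite] - np.min(aics[finite])
    ew = np.exp(-rel / 2.0)
    w[finite] = ew / ew.sum()
    return w


def fit_suite(
    doses,
    outcomes,
    families: Sequence = DEFAULT_SUITE,
    n_starts: int = 10,
    random_state=None,
    warm_starts: Optional[Sequence[Optional[np.ndarray]]] = None,
    ftol: float = 1e-13,
) -> ModelSuiteFit:
    """Fit every family and compute Akaike weights.

    Non-converged fits are excluded from the average (AIC treated as +inf).
    """
    ss = _as_seedseq(random_state)
    children = ss.spawn(len(families))
    fits = []
    for i, family in enumerate(families):
        warm = warm_starts[i] if warm_starts is not None else None
        fits.append(
            fit_model(
                doses, outcomes, family,
                n_starts=n_starts, random_state=children[i], warm_start=warm,
                ftol=ftol,
            )
        )
    aics = np.array([f.aic if f.converged else np.inf for f in fits])
    weights = akaike_weights(aics)
    return ModelSuiteFit(fits=fits, weights=weights)


def _as_seedseq(random_state) -> np.random.SeedSequence:
    if isinstance(random_state, np.random.SeedSequence):
        return random_state
    if isinstance(random_state, np.random.Generator):
        return np.random.SeedSequence(int(random_state.integers(2**31)))
    return np.random.SeedSequence(random_state)


# ---------------------------------------------------------------------------
# benchmark-dose inversion
# ---------------------------------------------------------------------------

def bmd_from_curve(
    curve: Callable[[np.ndarray], np.ndarray],
    bmr: float,
    risk_type: str = "extra",
    window: tuple[float, float] = (1e-6, 1e6),
    p0: Optional[float] = None,
    rtol: float = 1e-6,
    check_monotone: bool = True,
) -> tuple[float, Optional[str]]:
    """Invert a nondecreasing dose-response curve at the benchmark response.

    Solves ``P(BMD) = P0 + bmr*(1 - P0)`` (extra risk) by bisection on
    log-dose within ``window``.  Returns ``(dose, censoring)`` where
    ``censoring`` is None on success, ``"low"`` when the curve is already at
    or above the benchmark level at the lower window bound, and ``"high"``
    when it never reaches it inside the window; in both censored cases the
    returned dose is the corresponding window bound.

    Parameters
    ----------
    curve : callable
        Maps dose (array) to response probability.
    bmr : float
        Benchmark response as extra risk, in (0, 1).
    risk_type : str
        Only ``"extra"`` is supported.
    window : (low, high)
        Strictly positive search window for the dose.
    p0 : float, optional
        Background response; defaults to the curve evaluated at the lower
        window bound (a proxy for the d -> 0+ limit).
    rtol : float
        Relative tolerance on the dose.
    """
    if not 0.0 < bmr < 1.0:
        raise ValueError("bmr must lie in (0, 1)")
    if risk_type != "extra":
        raise ValueError(f"unsupported risk type {risk_type!r}")
    lo, hi = window
    if not (0.0 < lo < hi):
        raise ValueError("window must satisfy 0 < low < high")

    if check_monotone:
        grid = np.exp(np.linspace(np.log(lo), np.log(hi), 60))
        pg = np.asarray(curve(grid), dtype=float)
        if np.any(np.diff(pg) < -1e-9):
            raise ValueError("curve is not nondecreasing on the search window")

    if p0 is None:
        p0 = float(np.asarray(curve(np.array([lo])))[0])
    target = p0 + bmr * (1.0 - p0)

    f_lo = float(np.asarray(curve(np.array([lo])))[0]) - target
    f_hi = float(np.asarray(curve(np.array([hi])))[0]) - target
    if f_lo >= 0.0:
        return lo, "low"
    if f_hi < 0.0:
        return hi, "high"

    llo, lhi = np.log(lo), np.log(hi)
    for _ in range(200):
        mid = 0.5 * (llo + lhi)
        fm = float(np.asarray(curve(np.array([np.exp(mid)])))[0]) - target
        if fm >= 0.0:
            lhi = mid
        else:
            llo = mid
        if lhi - llo < rtol:
            break
    return float(np.exp(0.5 * (llo + lhi))), None


def bmdi_ratio(bmdl: float, bmdu: float) -> tuple[float, bool]:
    """BMDU/BMDL ratio and the "narrow interval" flag (ratio < 10)."""
    if not (0.0 < bmdl <= bmdu):
        raise ValueError("require 0 < bmdl <= bmdu")
    ratio = bmdu / bmdl
    return float(ratio), bool(ratio < _NARROW_RATIO)


# ---------------------------------------------------------------------------
# model averaging with parametric bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BMDResult:
    """Model-averaged BMD with bootstrap confidence limits and provenance."""

    bmd_ma: float
    bmdl: float
    bmdu: float
    ratio: float
    narrow: bool
    bmr: float
    risk_type: str
    n_boot: int
    seed: Optional[int]
    n: int
    n_censored_iterations: int
    n_nonconverged_iterations: int
    reliable: bool
    censoring: Optional[str]
    families: tuple[str, ...]
    weights: np.ndarray
    window: tuple[float, float]
    bootstrap_bmds: Optional[np.ndarray] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        """JSON-serializable summary (bootstrap sample omitted)."""
        return {
            "bmd_ma": float(self.bmd_ma),
            "bmdl": float(self.bmdl),
            "bmdu": float(self.bmdu),
            "ratio": float(self.ratio),
            "narrow": bool(self.narrow),
            "bmr": float(self.bmr),
            "risk_type": self.risk_type,
            "n_boot": int(self.n_boot),
            "seed": None if self.seed is None else int(self.seed),
            "n": int(self.n),
            "n_censored_iterations": int(self.n_censored_iterations),
            "n_nonconverged_iterations": int(self.n_nonconverged_iterations),
            "reliable": bool(self.reliable),
            "censoring": self.censoring,
            "families": list(self.families),
            "weights": [float(w) for w in self.weights],
            "window": [float(self.window[0]), float(self.window[1])],
        }


def _dose_window(d: np.ndarray) -> tuple[float, float]:
    return float(np.min(d)) * 1e-6, float(np.max(d)) * 1e6


def model_average_bmd(
    doses,
    outcomes,
    bmr: float = 0.10,
    n_boot: int = 200,
    seed: Optional[int] = None,
    families: Sequence = DEFAULT_SUITE,
    n_starts: int = 10,
    n_starts_boot: int = 0,
    risk_type: str = "extra",
    keep_samples: bool = False,
    keep_boot_fits: bool = False,
) -> BMDResult:
    """Model-averaged BMD with parametric-bootstrap BMDL/BMDU.

    Fits the full suite, weights by AIC, inverts the averaged curve at
    ``bmr`` extra risk, then redraws outcomes from the fitted averaged
    probabilities at the observed doses ``n_boot`` times, refitting the suite
    each time (warm-started from the original fits).  BMDL and BMDU are the
    5th and 95th percentiles of the bootstrap BMD sample; iterations whose
    curve never crosses the benchmark level inside the search window are
    recorded at the window bound and counted.  The result carries its seed
    and is fully reproducible.

    The result is flagged unreliable when more than half of the iterations
    are censored or non-converged.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    window = _dose_window(d)

    root = np.random.SeedSequence(seed)
    ss_fit, ss_boot = root.spawn(2)
    suite = fit_suite(d, y, families, n_starts=n_starts, random_state=ss_fit)
    ma = suite.curve()
    bmd_ma, censoring = bmd_from_curve(
        ma, bmr, risk_type, window=window, p0=suite.background(), check_monotone=False
    )

    rng = np.random.default_rng(ss_boot)
    p_hat = np.clip(np.asarray(ma(d), dtype=float), 0.0, 1.0)
    warm = [f.params if not f.degenerate else None for f in suite.fits]

    boot_bmds = np.empty(n_boot)
    boot_suites: list[ModelSuiteFit] = []
    n_censored = 0
    n_nonconv = 0
    boot_children = ss_boot.spawn(n_boot)
    for b in range(n_boot):
        y_star = (rng.random(d.size) < p_hat).astype(float)
        suite_b = fit_suite(
            d, y_star, families,
            n_starts=n_starts_boot, random_state=boot_children[b], warm_starts=warm,
            ftol=1e-10,
        )
        if not any(f.converged for f in suite_b.fits):
            n_nonconv += 1
        bmd_b, cens_b = bmd_from_curve(
            suite_b.curve(), bmr, risk_type, window=window,
            p0=suite_b.background(), check_monotone=False,
        )
        if cens_b is not None:
            n_censored += 1
        boot_bmds[b] = bmd_b
        if keep_boot_fits:
            boot_suites.append(suite_b)

    bmdl, bmdu = np.percentile(boot_bmds, [5.0, 95.0])
    bmdl = float(max(bmdl, window[0]))
    bmdu = float(max(bmdu, bmdl))
    ratio, narrow = bmdi_ratio(bmdl, bmdu)
    reliable = (n_censored + n_nonconv) <= 0.5 * n_boot

    result = BMDResult(
        bmd_ma=float(bmd_ma),
        bmdl=bmdl,
        bmdu=bmdu,
        ratio=ratio,
        narrow=narrow,
        bmr=bmr,
        risk_type=risk_type,
        n_boot=int(n_boot),
        seed=seed,
        n=int(d.size),
        n_censored_iterations=int(n_censored),
        n_nonconverged_iterations=int(n_nonconv),
        reliable=bool(reliable),
        censoring=censoring,
        families=tuple(get_family(f).name for f in families),
        weights=suite.weights,
        window=window,
        bootstrap_bmds=boot_bmds if keep_samples else None,
    )
    # attach the fitted suites for curve export / inspection
    result.suite = suite  # type: ignore[attr-defined]
    result.boot_suites = boot_suites if keep_boot_fits else None  # type: ignore[attr-defined]
    return result


def bootstrap_curve_export(
    result: BMDResult, dose_grid=None, n_grid: int = 50
) -> pd.DataFrame:
    """Model-averaged response curves on a log-spaced dose grid.

    Returns a long-format frame with columns ``curve`` ("estimate" or
    ``boot_####``), ``dose`` and ``response`` — one curve per retained
    bootstrap iteration plus the point-estimate curve, in the style of the
    usual bootstrap dose-response plots (log10 dose on x, quantal response on
    y).  Requires a result produced with ``keep_boot_fits=True`` for the
    bootstrap curves; otherwise only the point estimate is exported.
    """
    if dose_grid is None:
        lo, hi = result.window
        # span the observed-dose decade range rather than the full window
        dose_grid = np.logspace(np.log10(lo * 1e6) - 2, np.log10(hi / 1e6) + 2, n_grid)
    dose_grid = np.asarray(dose_grid, dtype=float)
    frames = []
    ma = result.suite.curve()  # type: ignore[attr-defined]
    frames.append(
        pd.DataFrame(
            {"curve": "estimate", "dose": dose_grid, "response": ma(dose_grid)}
        )
    )
    boot_suites = getattr(result, "boot_suites", None) or []
    for b, suite_b in enumerate(boot_suites):
        frames.append(
            pd.DataFrame(
                {
                    "curve": f"boot_{b:04d}",
                    "dose": dose_grid,
                    "response": suite_b.curve()(dose_grid),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class QuantalBMD(BaseEstimator):
    """Model-averaged quantal benchmark-dose estimator (sklearn API).

    ``fit(X, y)`` takes doses ``X`` (1-d, or a single-column 2-d array) and
    binary outcomes ``y`` (1 = outside the reference range), fits the model
    suite and runs the parametric bootstrap.  Fitted attributes follow the
    sklearn trailing-underscore convention.

    Parameters
    ----------
    bmr : float
        Benchmark response as extra risk (default 0.10).
    risk_type : str
        Risk convention; only ``"extra"``.
    families : sequence of str, optional
        Model suite (default: the seven-family classical quantal set).
    n_boot : int
        Bootstrap iterations for BMDL/BMDU (default 200).
    n_starts : int
        Multi-start count for the full-data fits.
    n_starts_boot : int
        Extra random starts per bootstrap refit (warm-started regardless).
    random_state : int, optional
        Seed; identical data + seed give identical results.
    keep_bootstrap_fits : bool
        Retain per-iteration suites for curve export.

    Attributes
    ----------
    result_ : BMDResult
    bmd_, bmdl_, bmdu_, ratio_, narrow_ : scalars
    fits_ : list of QuantalModelFit
    weights_ : ndarray of Akaike weights (sum to 1)
    """

    def __init__(
        self,
        bmr: float = 0.10,
        risk_type: str = "extra",
        families: Optional[Sequence[str]] = None,
        n_boot: int = 200,
        n_starts: int = 10,
        n_starts_boot: int = 0,
        random_state: Optional[int] = None,
        keep_bootstrap_fits: bool = False,
    ):
        self.bmr = bmr
        self.risk_type = risk_type
        self.families = families
        self.n_boot = n_boot
        self.n_starts = n_starts
        self.n_starts_boot = n_starts_boot
        self.random_state = random_state
        self.keep_bootstrap_fits = keep_bootstrap_fits

    @staticmethod
    def _as_dose(X) -> np.ndarray:
        d = np.asarray(X, dtype=float)
        if d.ndim == 2 and d.shape[1] == 1:
            d = d[:, 0]
        if d.ndim != 1:
            raise ValueError("X must be a 1-d dose vector or an (n, 1) array")
        return d

    def fit(self, X, y) -> "QuantalBMD":
        d = self._as_dose(X)
        self.result_ = model_average_bmd(
            d,
            np.asarray(y, dtype=float),
            bmr=self.bmr,
            n_boot=self.n_boot,
            seed=self.random_state,
            families=self.families or DEFAULT_SUITE,
            n_starts=self.n_starts,
            n_starts_boot=self.n_starts_boot,
            risk_type=self.risk_type,
            keep_samples=True,
            keep_boot_fits=self.keep_bootstrap_fits,
        )
        self.fits_ = self.result_.suite.fits  # type: ignore[attr-defined]
        self.weights_ = self.result_.weights
        self.bmd_ = self.result_.bmd_ma
        self.bmdl_ = self.result_.bmdl
        self.bmdu_ = self.result_.bmdu
        self.ratio_ = self.result_.ratio
        self.narrow_ = self.result_.narrow
        self.n_features_in_ = 1
        return self

    def ma_curve(self, dose) -> np.ndarray:
        """Model-averaged P(d) at the supplied doses."""
        if not hasattr(self, "result_"):
            raise AttributeError("QuantalBMD is not fitted yet")
        return self.result_.suite.curve()(np.asarray(dose, dtype=float))  # type: ignore[attr-defined]

    def predict_proba(self, X) -> np.ndarray:
        """(n, 2) class probabilities [P(in range), P(out of range)]."""
        p = self.ma_curve(self._as_dose(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
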