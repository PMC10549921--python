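"""Independent oracles used by the test suite.

Everything here is deliberately coded from first principles, separately from
the package implementation: direct transcriptions of the homeostasis
equations, a zooming grid search for maximum-likelihood checks, and an exact
permutation Spearman p-value for tiny samples.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import special


# ---------------------------------------------------------------------------
# SPINA equations, transcribed directly, all quantities in mol/L and mol/s
# ---------------------------------------------------------------------------

def spina_gt_direct(tsh_miu_per_l: float, ft4_pmol_per_l: float) -> float:
    """GT = betaT (DT + [TSH]) (1 + K41[TBG] + K42[TBPA]) [fT4] / (alphaT [TSH]),
    returned in pmol/s."""
    alpha_t = 0.1
    beta_t = 1.1e-6
    d_t = 2.75
    k41 = 2e10
    k42 = 2e8
    tbg_mol = 300e-9
    tbpa_mol = 4.5e-6
    ft4_mol = ft4_pmol_per_l * 1e-12
    gt_mol = (
        beta_t
        * (d_t + tsh_miu_per_l)
        * (1 + k41 * tbg_mol + k42 * tbpa_mol)
        * ft4_mol
        / (alpha_t * tsh_miu_per_l)
    )
    return gt_mol * 1e12


def spina_gd_direct(ft4_pmol_per_l: float, ft3_pmol_per_l: float) -> float:
    """GD = beta31 (KM1 + [fT4]) (1 + K30[TBG]) [fT3] / (alpha31 [fT4]),
    returned in nmol/s."""
    alpha_31 = 0.026
    beta_31 = 8e-6
    k_m1_mol = 500e-9
    k30 = 2e9
    tbg_mol = 300e-9
    ft4_mol = ft4_pmol_per_l * 1e-12
    ft3_mol = ft3_pmol_per_l * 1e-12
    gd_mol = (
        beta_31
        * (k_m1_mol + ft4_mol)
        * (1 + k30 * tbg_mol)
        * ft3_mol
        / (alpha_31 * ft4_mol)
    )
    return gd_mol * 1e9


T4_BINDING_FACTOR = 1 + 2e10 * 300e-9 + 2e8 * 4.5e-6  # = 6901
T3_TBG_FACTOR = 1 + 2e9 * 300e-9  # = 601


# ---------------------------------------------------------------------------
# independent dose-response probabilities (own transcription)
# ---------------------------------------------------------------------------

def prob_direct(family: str, params, d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow saturates correctly to 0/1
        return _prob_direct(family, params, d)


def _prob_direct(family: str, params, d: np.ndarray) -> np.ndarray:
    if family == "logistic":
        alpha, beta = params
        return 1.0 / (1.0 + np.exp(-(alpha + beta * d)))
    if family == "probit":
        alpha, beta = params
        return special.ndtr(alpha + beta * d)
    if family == "log_logistic":
        a, mu, sigma = params
        return a + (1 - a) / (1.0 + np.exp(-((np.log(d) - mu) / sigma)))
    if family == "log_probit":
        a, mu, sigma = params
        return a + (1 - a) * special.ndtr((np.log(d) - mu) / sigma)
    if family == "weibull":
        a, ln_b, c = params
        return a + (1 - a) * (1.0 - np.exp(-((d / np.exp(ln_b)) ** c)))
    if family == "gamma":
        a, ln_b, c = params
        return a + (1 - a) * special.gammainc(c, d / np.exp(ln_b))
    if family == "two_stage":
        a, b, c = params
        return a + (1 - a) * (1.0 - np.exp(-(b * d + c * d * d)))
    if family == "background":
        (a,) = params
        return np.full(d.shape, a)
    raise ValueError(family)


def loglik_direct(family: str, params, d: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(prob_direct(family, params, d), 1e-300, 1 - 1e-16)
    return float(np.sum(np.where(y == 1, np.log(p), np.log(1 - p))))


def grid_search_mle(
    family: str,
    bounds,
    d: np.ndarray,
    y: np.ndarray,
    n_coarse: int = 15,
    n_zoom: int = 9,
    n_rounds: int = 60,
    n_seeds: int = 3,
) -> float:
    """Best log-likelihood found by a coarse grid plus zooming refinement.

    The coarse pass scans the full box; the top ``n_seeds`` coarse points
    each seed an independent zoom (box shrunk by 0.6 per round around the
    running best), which drives the parameter resolution far below the
    curvature scale of the likelihood.
    """
    bounds = np.asarray(bounds, dtype=float)
    k = bounds.shape[0]

    axes = [np.linspace(lo, hi, n_coarse) for lo, hi in bounds]
    coarse = np.array(list(itertools.product(*axes)))
    lls = np.array([loglik_direct(family, p, d, y) for p in coarse])
    order = np.argsort(lls)[::-1]

    best_ll = -math.inf
    for seed_idx in order[:n_seeds]:
        center = coarse[seed_idx].copy()
        width = (bounds[:, 1] - bounds[:, 0]).astype(float)
        for _ in range(n_rounds):
            lo = np.maximum(center - width / 2, bounds[:, 0])
            hi = np.minimum(center + width / 2, bounds[:, 1])
            axes = [np.linspace(l, h, n_zoom) for l, h in zip(lo, hi)]
            pts = np.array(list(itertools.product(*axes)))
            vals = np.array([loglik_direct(family, p, d, y) for p in pts])
            j = int(np.argmax(vals))
            center = pts[j]
            width *= 0.6
        ll = loglik_direct(family, center, d, y)
        best_ll = max(best_ll, ll)
    return best_ll


# ---------------------------------------------------------------------------
# exact permutation Spearman p-value (n <= 10)
# ---------------------------------------------------------------------------

def spearman_exact_perm_p(x, y) -> float:
    """Two-sided permutation p-value of the Spearman correlation."""
    from scipy.stats import rankdata

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n > 10:
        raise ValueError("exact enumeration limited to n <= 10")
    rx = rankdata(x)
    ry = rankdata(y)

    def corr(a, b):
        return np.corrcoef(a, b)[0, 1]

    r_obs = abs(corr(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(corr(rx, ry[list(perm)]))
        count += r >= r_obs - 1e-12
        total += 1
    return count / total
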