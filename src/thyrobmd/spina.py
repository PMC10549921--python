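"""SPINA-GT and SPINA-GD thyroid homeostasis parameters.

SPINA-GT (secretory capacity, pmol/s) is the maximal T4 release rate of the
thyroid at full TSH stimulation::

    GT = beta_T * (D_T + [TSH]) * (1 + K41*[TBG] + K42*[TBPA]) * [fT4]
         / (alpha_T * [TSH])

SPINA-GD (sum activity of peripheral deiodinases, nmol/s) is the maximal T3
production capacity from T4::

    GD = beta_31 * (K_M1 + [fT4]) * (1 + K30*[TBG]) * [fT3]
         / (alpha_31 * [fT4])

Unit convention: TSH is taken in mIU/L (numerically identical to µIU/ml);
fT4 and fT3 in pmol/L.  All dissociation-constant products are evaluated in
mol/L (TBG nmol/L -> mol/L, TBPA µmol/L -> mol/L, K_M1 nmol/L -> mol/L), which
makes the binding factors dimensionless; GT is returned in pmol/s and GD in
nmol/s, matching the clinical reference ranges (GT 1.4–8.7 pmol/s, GD 20–60
nmol/s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import DEFAULT_CONSTANTS, SpinaConstants

__all__ = [
    "HormonePanel",
    "SpinaResult",
    "spina_gt",
    "spina_gd",
    "spina_panel",
    "attach_spina",
    "SpinaCalculator",
]

_NM = 1e-9   # nmol/L -> mol/L
_UM = 1e-6   # µmol/L -> mol/L
_PM = 1e-12  # pmol/L -> mol/L


@dataclass(frozen=True)
class HormonePanel:
    """One subject's serum panel; ``None`` marks a missing determination.

    Units: tsh µIU/ml (= mIU/L), ft4 pmol/L, ft3 pmol/L, t4 nmol/L, t3 nmol/L.
    """

    tsh: Optional[float] = None
    ft4: Optional[float] = None
    ft3: Optional[float] = None
    t4: Optional[float] = None
    t3: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("tsh", "ft4", "ft3", "t4", "t3"):
            value = getattr(self, name)
            if value is not None and np.isfinite(value) and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")


@dataclass(frozen=True)
class SpinaResult:
    """Computed homeostasis parameters; ``None`` where inputs were missing."""

    gt: Optional[float] = None  # pmol/s
    gd: Optional[float] = None  # nmol/s


def _t4_binding_factor(constants: SpinaConstants) -> float:
    """Dimensionless plasma-protein binding factor for T4 (6901 at defaults)."""
    return 1.0 + constants.k41 * constants.tbg * _NM + constants.k42 * constants.tbpa * _UM


def _t3_binding_factor(constants: SpinaConstants) -> float:
    """Dimensionless TBG binding factor for T3 (601 at defaults)."""
    return 1.0 + constants.k30 * constants.tbg * _NM


def spina_gt(tsh, ft4, constants: SpinaConstants = DEFAULT_CONSTANTS):
    """Thyroid secretory capacity SPINA-GT in pmol/s.

    Parameters
    ----------
    tsh : float or array-like
        Serum TSH in mIU/L (µIU/ml); must be strictly positive.
    ft4 : float or array-like
        Serum free T4 in pmol/L; must be non-negative.
    constants : SpinaConstants
        Model constants; defaults are the standard SPINA values.
    """
    tsh = np.asarray(tsh, dtype=float)
    ft4 = np.asarray(ft4, dtype=float)
    if np.any(tsh <= 0):
        raise ValueError("spina_gt requires tsh > 0 (division by alpha_T*TSH)")
    if np.any(ft4 < 0):
        raise ValueError("spina_gt requires ft4 >= 0")
    binding = _t4_binding_factor(constants)
    gt_mol = (
        constants.beta_t
        * (constants.d_t + tsh)
        * binding
        * (ft4 * _PM)
        / (constants.alpha_t * tsh)
    )
    out = gt_mol / _PM  # mol/s -> pmol/s
    return float(out) if out.ndim == 0 else out


def spina_gd(ft4, ft3, constants: SpinaConstants = DEFAULT_CONSTANTS):
    """Sum activity of peripheral deiodinases SPINA-GD in nmol/s.

    Parameters
    ----------
    ft4 : float or array-like
        Serum free T4 in pmol/L; must be strictly positive.
    ft3 : float or array-like
        Serum free T3 in pmol/L; must be non-negative.
    constants : SpinaConstants
        Model constants.
    """
    ft4 = np.asarray(ft4, dtype=float)
    ft3 = np.asarray(ft3, dtype=float)
    if np.any(ft4 <= 0):
        raise ValueError("spina_gd requires ft4 > 0")
    if np.any(ft3 < 0):
        raise ValueError("spina_gd requires ft3 >= 0")
    gd_mol = (
        constants.beta_31
        * (constants.k_m1 * _NM + ft4 * _PM)
        * _t3_binding_factor(constants)
        * (ft3 * _PM)
        / (constants.alpha_31 * (ft4 * _PM))
    )
    out = gd_mol / _NM  # mol/s -> nmol/s
    return float(out) if out.ndim == 0 else out


def _usable(value: Optional[float]) -> bool:
    return value is not None and np.isfinite(value)


def spina_panel(
    panel: HormonePanel, constants: SpinaConstants = DEFAULT_CONSTANTS
) -> SpinaResult:
    """Apply both SPINA equations to a panel, propagating missingness.

    GT is missing when TSH or fT4 is missing (or TSH is non-positive, which
    leaves the equation undefined); GD is missing when fT4 or fT3 is missing
    or fT4 is zero.
    """
    gt = None
    gd = None
    if _usable(panel.tsh) and _usable(panel.ft4) and panel.tsh > 0:
        gt = spina_gt(panel.tsh, panel.ft4, constants)
    if _usable(panel.ft4) and _usable(panel.ft3) and panel.ft4 > 0:
        gd = spina_gd(panel.ft4, panel.ft3, constants)
    return SpinaResult(gt=gt, gd=gd)


def attach_spina(
    frame: pd.DataFrame, constants: SpinaConstants = DEFAULT_CONSTANTS
) -> pd.DataFrame:
    """Return a copy of ``frame`` with ``spina_gt``/``spina_gd`` columns added.

    Requires columns ``tsh``, ``ft4``, ``ft3``; missing (NaN) or out-of-domain
    inputs yield NaN results row-wise rather than raising.
    """
    out = frame.copy()

    def column(name: str) -> np.ndarray:
        if name in out.columns:
            return out[name].to_numpy(dtype=float)
        return np.full(len(out), np.nan)  # absent column = all missing

    tsh = column("tsh")
    ft4 = column("ft4")
    ft3 = column("ft3")

    gt = np.full(len(out), np.nan)
    ok_gt = np.isfinite(tsh) & np.isfinite(ft4) & (tsh > 0) & (ft4 >= 0)
    if ok_gt.any():
        gt[ok_gt] = spina_gt(tsh[ok_gt], ft4[ok_gt], constants)

    gd = np.full(len(out), np.nan)
    ok_gd = np.isfinite(ft4) & np.isfinite(ft3) & (ft4 > 0) & (ft3 >= 0)
    if ok_gd.any():
        gd[ok_gd] = spina_gd(ft4[ok_gd], ft3[ok_gd], constants)

    out["spina_gt"] = gt
    out["spina_gd"] = gd
    return out


class SpinaCalculator(TransformerMixin, BaseEstimator):
    """Stateless transformer adding SPINA-GT/GD columns to a cohort frame.

    Composes with sklearn pipelines; ``fit`` is a no-op.

    Parameters
    ----------
    constants : SpinaConstants, optional
        Overrides for the model constants (defaults: standard SPINA values).
    """

    def __init__(self, constants: SpinaConstants = DEFAULT_CONSTANTS):
        self.constants = constants

    def fit(self, X: pd.DataFrame, y=None) -> "SpinaCalculator":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("SpinaCalculator expects a pandas DataFrame")
        missing = {"tsh", "ft4", "ft3"} - set(X.columns)
        if missing:
            raise ValueError(f"missing hormone column(s): {sorted(missing)}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return attach_spina(X, self.constants)
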