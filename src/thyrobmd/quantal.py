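"""Reference-range quantalization of cohort endpoints.

Each continuous endpoint value is reduced to a binary indicator: 0 when the
value lies inside its clinical reference range (boundaries inclusive), 1 when
it lies outside.  Missing determinations stay missing and are dropped per
endpoint, not per subject, so endpoint row totals may differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import ENDPOINTS, REFERENCE_RANGES

__all__ = [
    "ReferenceRangeSet",
    "QuantalEndpointTable",
    "classify",
    "quantalize_cohort",
    "RangeQuantalizer",
]


@dataclass(frozen=True)
class ReferenceRangeSet:
    """Mapping endpoint name -> (low, high) reference interval.

    Both bounds are inclusive.  Defaults cover the seven standard endpoints.
    """

    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(REFERENCE_RANGES)
    )

    def __post_init__(self) -> None:
        for name, (low, high) in self.ranges.items():
            if not low < high:
                raise ValueError(
                    f"reference range for {name!r} must satisfy low < high, "
                    f"got ({low}, {high})"
                )

    def __getitem__(self, endpoint: str) -> tuple[float, float]:
        return self.ranges[endpoint]

    def __contains__(self, endpoint: str) -> bool:
        return endpoint in self.ranges

    @property
    def endpoints(self) -> tuple[str, ...]:
        return tuple(self.ranges)

    def with_overrides(
        self, overrides: Mapping[str, tuple[float, float]]
    ) -> "ReferenceRangeSet":
        merged = dict(self.ranges)
        merged.update({k: tuple(v) for k, v in overrides.items()})
        return ReferenceRangeSet(merged)


def classify(value, rng: tuple[float, float]):
    """Quantal indicator: 0 iff ``low <= value <= high``, else 1.

    Scalar or array input; NaN (missing) maps to NaN, infinite values raise.
    """
    low, high = rng
    arr = np.asarray(value, dtype=float)
    if np.any(np.isinf(arr)):
        raise ValueError("classify requires finite values (got ±inf)")
    out = np.where((arr >= low) & (arr <= high), 0.0, 1.0)
    out = np.where(np.isnan(arr), np.nan, out)
    if arr.ndim == 0:
        return float(out)
    return out


@dataclass
class QuantalEndpointTable:
    """Per subject × endpoint quantal indicators with stratum labels.

    ``indicators`` holds 0.0 / 1.0 / NaN; ``strata`` carries the stratum label
    of each subject (aligned index).
    """

    indicators: pd.DataFrame
    strata: pd.Series

    def counts(self) -> pd.DataFrame:
        """In/out/missing counts per endpoint and stratum (Table-3 layout).

        For every endpoint and stratum, ``n_in + n_out + n_missing`` equals
        the stratum size.
        """
        rows = []
        for stratum, idx in self.strata.groupby(self.strata).groups.items():
            sub = self.indicators.loc[idx]
            for endpoint in self.indicators.columns:
                col = sub[endpoint]
                rows.append(
                    {
                        "endpoint": endpoint,
                        "stratum": stratum,
                        "n_in": int((col == 0).sum()),
                        "n_out": int((col == 1).sum()),
                        "n_missing": int(col.isna().sum()),
                        "n_total": int(len(col)),
                    }
                )
        return pd.DataFrame(rows)


def quantalize_cohort(
    cohort: pd.DataFrame,
    ranges: Optional[ReferenceRangeSet] = None,
    endpoints: Optional[Iterable[str]] = None,
    stratum_col: str = "sex",
) -> QuantalEndpointTable:
    """Quantalize every endpoint column of a cohort frame.

    Parameters
    ----------
    cohort : DataFrame
        Must contain the endpoint columns (SPINA values already attached) and
        the stratum column.
    ranges : ReferenceRangeSet, optional
        Reference intervals; defaults to the standard seven.
    endpoints : iterable of str, optional
        Endpoints to quantalize; defaults to every endpoint in ``ranges``
        that is present as a column.
    stratum_col : str
        Column carrying the stratum label (default ``"sex"``).
    """
    ranges = ranges or ReferenceRangeSet()
    if endpoints is None:
        endpoints = [e for e in ranges.endpoints if e in cohort.columns]
    else:
        endpoints = list(endpoints)
    unknown = [e for e in endpoints if e not in ranges]
    if unknown:
        raise ValueError(f"no reference range configured for endpoint(s): {unknown}")
    absent = [e for e in endpoints if e not in cohort.columns]
    if absent:
        raise ValueError(f"cohort lacks endpoint column(s): {absent}")

    data = {
        e: classify(cohort[e].to_numpy(dtype=float), ranges[e]) for e in endpoints
    }
    indicators = pd.DataFrame(data, index=cohort.index)
    strata = cohort[stratum_col] if stratum_col in cohort.columns else pd.Series(
        "all", index=cohort.index, name="stratum"
    )
    return QuantalEndpointTable(indicators=indicators, strata=strata)


class RangeQuantalizer(TransformerMixin, BaseEstimator):
    """Transformer mapping endpoint columns to 0/1/NaN indicators.

    Parameters
    ----------
    ranges : ReferenceRangeSet, optional
        Reference intervals keyed by column name; columns without a configured
        range pass through unchanged when ``passthrough`` is true, else raise.
    passthrough : bool
        Keep non-endpoint columns as-is (default True).
    """

    def __init__(self, ranges: Optional[ReferenceRangeSet] = None, passthrough: bool = True):
        self.ranges = ranges
        self.passthrough = passthrough

    def fit(self, X: pd.DataFrame, y=None) -> "RangeQuantalizer":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("RangeQuantalizer expects a pandas DataFrame")
        ranges = self.ranges or ReferenceRangeSet()
        self.endpoints_ = [c for c in X.columns if c in ranges]
        if not self.passthrough:
            extra = [c for c in X.columns if c not in ranges]
            if extra:
                raise ValueError(f"no reference range for column(s): {extra}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        ranges = self.ranges or ReferenceRangeSet()
        out = X.copy()
        for endpoint in self.endpoints_:
            out[endpoint] = classify(X[endpoint].to_numpy(dtype=float), ranges[endpoint])
        return out
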