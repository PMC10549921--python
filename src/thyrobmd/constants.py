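"""Physical constants and clinical reference ranges for thyroid homeostasis.

The SPINA (structure parameter inference approach) equations estimate two
aggregate parameters of the hypothalamus–pituitary–thyroid axis from a serum
hormone panel: GT, the maximal thyroid secretory capacity, and GD, the summed
activity of peripheral type-1 deiodinases.  Both are algebraic functions of
measured hormone concentrations and a set of kinetic and plasma-protein-binding
constants, collected here in :class:`SpinaConstants`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping


@dataclass(frozen=True)
class SpinaConstants:
    """Kinetic and binding constants of the SPINA thyroid model.

    Attributes
    ----------
    alpha_t : float
        Dilution factor for thyroxine (1/L).
    beta_t : float
        Clearance exponent for T4 (1/s).
    d_t : float
        EC50 of TSH at the thyroid gland (mIU/L).
    k41 : float
        Dissociation constant of T4 at thyroxine-binding globulin (L/mol).
    k42 : float
        Dissociation constant of T4 at transthyretin (L/mol).
    alpha_31 : float
        Dilution factor for triiodothyronine (1/L).
    beta_31 : float
        Clearance exponent for T3 (1/s).
    k_m1 : float
        Dissociation (Michaelis) constant of type-1 deiodinase (nmol/L).
    k30 : float
        Dissociation constant of T3 at thyroxine-binding globulin (L/mol).
    tbg : float
        Standard thyroxine-binding globulin concentration (nmol/L).
    tbpa : float
        Standard transthyretin (TBPA) concentration (µmol/L).
    beta_corr : float
        Correction coefficient of the logarithmic model (dimensionless).
        Carried for completeness; not used by the GT/GD equations.
    """

    alpha_t: float = 0.1
    beta_t: float = 1.1e-6
    d_t: float = 2.75
    k41: float = 2e10
    k42: float = 2e8
    alpha_31: float = 0.026
    beta_31: float = 8e-6
    k_m1: float = 500.0
    k30: float = 2e9
    tbg: float = 300.0
    tbpa: float = 4.5
    beta_corr: float = 0.1345

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if not (value > 0):
                raise ValueError(
                    f"SPINA constant {field.name!r} must be strictly positive, "
                    f"got {value!r}"
                )

    def replace(self, **overrides: float) -> "SpinaConstants":
        """Return a copy with selected constants overridden."""
        return dataclasses.replace(self, **overrides)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "SpinaConstants":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown SPINA constant(s): {sorted(unknown)}")
        return cls(**dict(mapping))

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


DEFAULT_CONSTANTS = SpinaConstants()

#: Endpoint names in canonical order: the five measured serum quantities
#: followed by the two computed homeostasis parameters.
ENDPOINTS: tuple[str, ...] = (
    "tsh",
    "ft4",
    "ft3",
    "t4",
    "t3",
    "spina_gt",
    "spina_gd",
)

#: Measured hormone columns of a cohort table (SPINA endpoints are derived).
HORMONES: tuple[str, ...] = ("tsh", "ft4", "ft3", "t4", "t3")

#: Clinical reference ranges, (low, high), in each endpoint's units:
#: TSH µIU/ml, fT4 pmol/L, fT3 pmol/L, T4 nmol/L, T3 nmol/L,
#: SPINA-GT pmol/s, SPINA-GD nmol/s.
REFERENCE_RANGES: dict[str, tuple[float, float]] = {
    "tsh": (0.270, 4.20),
    "ft4": (12.0, 22.0),
    "ft3": (3.1, 6.8),
    "t4": (66.0, 181.0),
    "t3": (1.3, 3.1),
    "spina_gt": (1.4, 8.7),
    "spina_gd": (20.0, 60.0),
}

#: Display units per endpoint (used in report headers).
ENDPOINT_UNITS: dict[str, str] = {
    "tsh": "µIU/ml",
    "ft4": "pmol/L",
    "ft3": "pmol/L",
    "t4": "nmol/L",
    "t3": "nmol/L",
    "spina_gt": "pmol/s",
    "spina_gd": "nmol/s",
}
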