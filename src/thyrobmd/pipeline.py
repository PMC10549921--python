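"""End-to-end analysis pipeline: cohort CSV in, report tables out.

Stages: read and validate the cohort, attach SPINA-GT/GD, quantalize against
the reference ranges, compute per-stratum descriptives and Spearman
correlations with nickel, and run stratified model-averaged BMD analyses
(men / women / entire population, plus healthy / unhealthy strata for the
SPINA endpoints).  Every BMD cell carries its own deterministic seed derived
from the run seed and the (endpoint, stratum) labels, so re-running a single
stage reproduces the full-run numbers exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bmd import bootstrap_curve_export, model_average_bmd
from .constants import DEFAULT_CONSTANTS, ENDPOINTS, SpinaConstants
from .descriptives import correlation_table, fraction_above, summary_table
from .families import DEFAULT_SUITE
from .quantal import QuantalEndpointTable, ReferenceRangeSet, quantalize_cohort
from .spina import attach_spina

__all__ = ["RunConfig", "AnalysisReport", "read_cohort", "run_pipeline"]

logger = logging.getLogger("thyrobmd")

_SEX_ALIASES = {
    "m": "M", "male": "M", "man": "M", "men": "M",
    "f": "F", "female": "F", "woman": "F", "women": "F",
}

_MANDATORY_COLUMNS = ("id", "sex", "ni")
_HORMONE_COLUMNS = ("tsh", "ft4", "ft3", "t4", "t3")


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one pipeline run."""

    input: Optional[str] = None
    outdir: Optional[str] = None
    endpoints: Sequence[str] = ENDPOINTS
    reference_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    constants: SpinaConstants = DEFAULT_CONSTANTS
    sex_strata: Sequence[str] = ("M", "F", "entire")
    health_strata: bool = True
    health_endpoints: Sequence[str] = ("spina_gt", "spina_gd")
    families: Sequence[str] = DEFAULT_SUITE
    bmr: float = 0.10
    n_boot: int = 200
    n_starts: int = 10
    n_starts_boot: int = 0
    seed: int = 0
    export_curves: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.bmr < 1.0:
            raise ValueError("bmr must lie in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        if "constants" in raw and not isinstance(raw["constants"], SpinaConstants):
            raw["constants"] = SpinaConstants.from_dict(raw["constants"])
        if "reference_ranges" in raw:
            raw["reference_ranges"] = {
                k: tuple(v) for k, v in raw["reference_ranges"].items()
            }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["constants"] = self.constants.to_dict()
        out["endpoints"] = list(self.endpoints)
        out["sex_strata"] = list(self.sex_strata)
        out["health_endpoints"] = list(self.health_endpoints)
        out["families"] = list(self.families)
        out["reference_ranges"] = {
            k: list(v) for k, v in dict(self.reference_ranges).items()
        }
        return out

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Expected columns (decimal points, empty cells = missing): ``id``,
    ``sex``, ``ni`` (mandatory), optionally ``age``, ``group`` and the
    hormone columns ``tsh, ft4, ft3, t4, t3`` in the standard units.
    Sex labels such as "male"/"female" are normalized to M/F.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"cohort file {path} is empty") from None
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    missing = [c for c in _MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort file lacks mandatory column(s): {missing}")

    sex = frame["sex"].astype(str).str.strip().str.lower().map(_SEX_ALIASES)
    bad_sex = frame.index[sex.isna()]
    if len(bad_sex):
        raise ValueError(
            f"unrecognized sex label at row(s) {list(bad_sex[:5])}; "
            "expected M/F (or male/female)"
        )
    frame["sex"] = sex

    for col in ("ni",) + _HORMONE_COLUMNS:
        if col not in frame.columns:
            continue
        values = pd.to_numeric(frame[col], errors="coerce")
        negative = frame.index[values < 0]
        if len(negative):
            raise ValueError(
                f"negative concentration in column {col!r} at row index "
                f"{int(negative[0])}"
            )
        frame[col] = values
    if frame["ni"].isna().all():
        raise ValueError("no usable nickel measurements in cohort")
    return frame


def _cell_seed(base_seed: int, endpoint: str, stratum: str) -> int:
    """Deterministic per-(endpoint, stratum) seed below 2**31."""
    ss = np.random.SeedSequence(
        [int(base_seed), zlib.crc32(endpoint.encode()), zlib.crc32(stratum.encode())]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _strata_frames(cohort: pd.DataFrame, config: RunConfig):
    for label in config.sex_strata:
        if label == "entire":
            yield "entire", cohort
        else:
            yield label, cohort[cohort["sex"] == label]
    if config.health_strata and "group" in cohort.columns:
        for label in ("healthy", "unhealthy"):
            yield label, cohort[cohort["group"] == label]


@dataclass
class AnalysisReport:
    """All tables produced by one pipeline run, plus provenance."""

    counts: pd.DataFrame
    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    bmd_table: pd.DataFrame
    exceedance: pd.DataFrame
    provenance: dict
    curves: Optional[pd.DataFrame] = None

    def to_json(self) -> str:
        """Deterministic JSON serialization of the full report."""
        payload = {
            "provenance": self.provenance,
            "counts": self.counts.to_dict(orient="records"),
            "descriptives": self.descriptives.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
            "bmd": self.bmd_table.to_dict(orient="records"),
            "exceedance": self.exceedance.to_dict(orient="records"),
        }
        return json.dumps(_jsonable(payload), sort_keys=True, indent=1)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.csv", index=False)
        self.descriptives.to_csv(outdir / "descriptives.csv", index=False)
        self.correlations.to_csv(outdir / "correlations.csv", index=False)
        self.bmd_table.to_csv(outdir / "bmd.csv", index=False)
        self.exceedance.to_csv(outdir / "exceedance.csv", index=False)
        if self.curves is not None:
            self.curves.to_csv(outdir / "curves.csv", index=False)
        (outdir / "report.json").write_text(self.to_json())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _bmd_cell(
    cohort: pd.DataFrame,
    quantal: QuantalEndpointTable,
    endpoint: str,
    stratum: str,
    index,
    config: RunConfig,
    collect_curves: bool,
):
    sub = quantal.indicators.loc[index, endpoint]
    dose = cohort.loc[index, "ni"]
    keep = sub.notna() & dose.notna() & (dose > 0)
    y = sub[keep].to_numpy(dtype=float)
    d = dose[keep].to_numpy(dtype=float)
    base = {"endpoint": endpoint, "stratum": stratum, "n": int(len(y)),
            "n_out": int(y.sum()) if len(y) else 0}
    if len(y) < 10 or y.min() == y.max():
        logger.info("BMD %s/%s: not estimable (n=%d)", endpoint, stratum, len(y))
        return {**base, "status": "not_estimable", "bmd_ma": np.nan,
                "bmdl": np.nan, "bmdu": np.nan, "ratio": np.nan,
                "narrow": False, "seed": np.nan, "n_censored_iterations": np.nan,
                "reliable": False}, None
    seed = _cell_seed(config.seed, endpoint, stratum)
    result = model_average_bmd(
        d, y,
        bmr=config.bmr, n_boot=config.n_boot, seed=seed,
        families=config.families, n_starts=config.n_starts,
        n_starts_boot=config.n_starts_boot, keep_boot_fits=collect_curves,
    )
    logger.info(
        "BMD %s/%s: n=%d bmd=%.4g bmdl=%.4g bmdu=%.4g censored=%d",
        endpoint, stratum, len(y), result.bmd_ma, result.bmdl, result.bmdu,
        result.n_censored_iterations,
    )
    row = {**base, "status": "ok", "bmd_ma": result.bmd_ma,
           "bmdl": result.bmdl, "bmdu": result.bmdu, "ratio": result.ratio,
           "narrow": result.narrow, "seed": seed,
           "n_censored_iterations": result.n_censored_iterations,
           "reliable": result.reliable}
    curves = None
    if collect_curves:
        curves = bootstrap_curve_export(result)
        curves.insert(0, "endpoint", endpoint)
        curves.insert(1, "stratum", stratum)
    return row, curves


def run_pipeline(config: RunConfig, cohort: Optional[pd.DataFrame] = None) -> AnalysisReport:
    """Run the full analysis and return the report.

    ``cohort`` may be supplied directly (e.g. from the synthetic generator);
    otherwise it is read from ``config.input``.  Deterministic given
    (cohort, config): every stochastic stage is seeded from ``config.seed``.
    """
    if cohort is None:
        if config.input is None:
            raise ValueError("config.input is required when no cohort is supplied")
        cohort = read_cohort(config.input)
    logger.info("cohort: %d subjects (%s)", len(cohort),
                cohort["sex"].value_counts().to_dict())

    cohort = attach_spina(cohort, config.constants)
    ranges = ReferenceRangeSet().with_overrides(dict(config.reference_ranges))
    endpoints = [e for e in config.endpoints if e in cohort.columns]
    quantal = quantalize_cohort(cohort, ranges, endpoints)
    counts = quantal.counts()
    logger.info("quantalized %d endpoints", len(endpoints))

    descr = summary_table(cohort, ["ni", *endpoints])
    corr = correlation_table(cohort, "ni", endpoints)

    bmd_rows = []
    curve_frames = []
    for stratum, sub in _strata_frames(cohort, config):
        stratum_endpoints = (
            config.health_endpoints
            if stratum in ("healthy", "unhealthy")
            else endpoints
        )
        for endpoint in stratum_endpoints:
            row, curves = _bmd_cell(
                cohort, quantal, endpoint, stratum, sub.index, config,
                collect_curves=config.export_curves,
            )
            bmd_rows.append(row)
            if curves is not None:
                curve_frames.append(curves)
    bmd_table = pd.DataFrame(bmd_rows)

    # exceedance: percent of each sex stratum above each estimable BMDL
    exceed_rows = []
    for _, row in bmd_table.iterrows():
        if row["status"] != "ok" or not np.isfinite(row["bmdl"]):
            continue
        stratum = row["stratum"]
        if stratum == "entire":
            values = cohort["ni"]
        elif stratum in ("healthy", "unhealthy"):
            values = cohort.loc[cohort["group"] == stratum, "ni"]
        else:
            values = cohort.loc[cohort["sex"] == stratum, "ni"]
        values = values.dropna()
        if values.empty:
            continue
        exceed_rows.append(
            {
                "endpoint": row["endpoint"],
                "stratum": stratum,
                "bmdl": row["bmdl"],
                "pct_above_bmdl": fraction_above(values, row["bmdl"]),
            }
        )
    exceedance = pd.DataFrame(exceed_rows)

    provenance = {
        "software": "thyrobmd",
        "version": __version__,
        "seed": int(config.seed),
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_subjects": int(len(cohort)),
    }
    report = AnalysisReport(
        counts=counts,
        descriptives=descr,
        correlations=corr,
        bmd_table=bmd_table,
        exceedance=exceedance,
        provenance=provenance,
        curves=pd.concat(curve_frames, ignore_index=True) if curve_frames else None,
    )
    if config.outdir:
        report.write(config.outdir)
    return report
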