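"""Derived surface-area and volume metrics for digitised coral colonies.

A colony is measured four ways: the whole colony underwater before and
after a fragment is chiselled off ("unsampled" / "sampled"), and the
collected fragment on land with fresh tissue and again after bleaching
to bare skeleton.  Each model yields a total surface area (TSA), an
effective surface area (ESA, living tissue only), and — when the mesh is
a coherent solid — a total volume (TV).  The derived suite compares them:

========================  ====================================================
ThSA / ThV                Unsampled − Sampled (underwater): the indirect
                          digital estimate of the removed fragment's SA / V.
Biosurface / Biomass      Tissue − Skeleton (dry): proxies for the living
                          tissue's surface and volume.  May be negative
                          (mucus films, epiphytes).
% Scale                   Tissue ESA (or TV) as a percentage of the
                          unsampled colony: the sample-to-colony size ratio.
Theoretical Error         Relative error of ThSA against ESA Tissue (or ThV
                          against TV Tissue): the pipeline's accuracy check.
Error TVW                 Relative discrepancy of digital skeleton volume
                          against water-displacement volume.
========================  ====================================================

Missing raw measurements (volumes of growth forms that never reconstruct
as solids) propagate to missing derived values, never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import pandas as pd

__all__ = [
    "GROWTH_FORMS",
    "ColonyMeasurements",
    "MetricReport",
    "theoretic_sa",
    "theoretic_v",
    "biosurface",
    "biomass",
    "pct_scale_sa",
    "pct_scale_v",
    "theoretical_error_sa",
    "theoretical_error_v",
    "error_tvw",
    "full_report",
    "read_measurements_csv",
    "write_measurements_csv",
    "report_table",
    "REPORT_COLUMNS",
]

GROWTH_FORMS = ("massive", "branched", "tabular", "crustose", "foliose")

_OPTIONAL_RAW = {"unsampled_sa", "tsa_sampled", "esa_sampled", "unsampled_v", "tv_sampled", "tv_water"}


@dataclass(frozen=True)
class ColonyMeasurements:
    """Raw (non-derived) measurements of one colony, in cm² / cm³.

    ``None`` encodes a measurement that could not be made — e.g. underwater
    volumes of colonies whose models were not watertight.
    """

    name: str
    growth_form: str
    tsa_tissue: float
    esa_tissue: float
    tsa_skeleton: float
    esa_skeleton: float
    tv_tissue: float
    tv_skeleton: float
    unsampled_sa: Optional[float] = None
    tsa_sampled: Optional[float] = None
    esa_sampled: Optional[float] = None
    unsampled_v: Optional[float] = None
    tv_sampled: Optional[float] = None
    tv_water: Optional[float] = None

    def __post_init__(self):
        if self.growth_form not in GROWTH_FORMS:
            raise ValueError(
                f"unknown growth form {self.growth_form!r}; expected one of {GROWTH_FORMS}"
            )
        for f in fields(self):
            if f.name in ("name", "growth_form"):
                continue
            v = getattr(self, f.name)
            if v is None:
                continue
            v = float(v)
            if math.isnan(v):
                object.__setattr__(self, f.name, None)
                continue
            if v < 0:
                raise ValueError(f"raw measurement {f.name} must be >= 0, got {v}")
            object.__setattr__(self, f.name, v)


@dataclass(frozen=True)
class MetricReport:
    """All derived quantities for one colony; ``None`` mirrors a "-" cell."""

    name: str
    growth_form: str
    thsa: Optional[float]
    thv: Optional[float]
    biosurface: Optional[float]
    biomass: Optional[float]
    pct_scale_sa: Optional[float]
    pct_scale_v: Optional[float]
    theoretical_error_sa: Optional[float]
    theoretical_error_v: Optional[float]
    error_tvw: Optional[float]


def _diff(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None or b is None:
        return None
    return a - b


def _pct(num: Optional[float], den: Optional[float]) -> Optional[float]:
    if num is None or den is None or den <= 0:
        return None
    return 100.0 * num / den


def _rel_err(value: Optional[float], reference: Optional[float]) -> Optional[float]:
    if value is None or reference is None or reference <= 0:
        return None
    return 100.0 * abs(value - reference) / reference


def theoretic_sa(m: ColonyMeasurements) -> Optional[float]:
    """ThSA = Unsampled SA − ESA Sampled (cm², signed)."""
    return _diff(m.unsampled_sa, m.esa_sampled)


def theoretic_v(m: ColonyMeasurements) -> Optional[float]:
    """ThV = Unsampled V − TV Sampled (cm³, signed)."""
    return _diff(m.unsampled_v, m.tv_sampled)


def biosurface(m: ColonyMeasurements) -> Optional[float]:
    """Biosurface = TSA Tissue − TSA Skeleton (cm², signed)."""
    return _diff(m.tsa_tissue, m.tsa_skeleton)


def biomass(m: ColonyMeasurements) -> Optional[float]:
    """Biomass = TV Tissue − TV Skeleton (cm³, signed)."""
    return _diff(m.tv_tissue, m.tv_skeleton)


def pct_scale_sa(m: ColonyMeasurements) -> Optional[float]:
    """% Scale (SA) = 100 · ESA Tissue / Unsampled SA."""
    return _pct(m.esa_tissue, m.unsampled_sa)


def pct_scale_v(m: ColonyMeasurements) -> Optional[float]:
    """% Scale (V) = 100 · TV Tissue / Unsampled V."""
    return _pct(m.tv_tissue, m.unsampled_v)


def theoretical_error_sa(m: ColonyMeasurements) -> Optional[float]:
    """100 · |ThSA − ESA Tissue| / ESA Tissue."""
    return _rel_err(theoretic_sa(m), m.esa_tissue)


def theoretical_error_v(m: ColonyMeasurements) -> Optional[float]:
    """100 · |ThV − TV Tissue| / TV Tissue."""
    return _rel_err(theoretic_v(m), m.tv_tissue)


def error_tvw(m: ColonyMeasurements) -> Optional[float]:
    """100 · |TV Skeleton − TV Water| / TV Water.

    The water-displacement volume is the denominator; this is the
    convention that reproduces published reference values of this metric.
    """
    return _rel_err(m.tv_skeleton, m.tv_water)


def full_report(m: ColonyMeasurements) -> MetricReport:
    """Every derived quantity for one colony, at full precision.

    Pure: identical measurements give identical reports.  Values are only
    rounded at serialization (2 decimals).
    """
    return MetricReport(
        name=m.name,
        growth_form=m.growth_form,
        thsa=theoretic_sa(m),
        thv=theoretic_v(m),
        biosurface=biosurface(m),
        biomass=biomass(m),
        pct_scale_sa=pct_scale_sa(m),
        pct_scale_v=pct_scale_v(m),
        theoretical_error_sa=theoretical_error_sa(m),
        theoretical_error_v=theoretical_error_v(m),
        error_tvw=error_tvw(m),
    )


# ---------------------------------------------------------------------------
# CSV I/O (comma, UTF-8, '.' decimal, empty cell = absent)

_RAW_COLUMNS = [
    "name",
    "growth_form",
    "unsampled_sa",
    "tsa_sampled",
    "esa_sampled",
    "tsa_tissue",
    "esa_tissue",
    "tsa_skeleton",
    "esa_skeleton",
    "unsampled_v",
    "tv_sampled",
    "tv_tissue",
    "tv_skeleton",
    "tv_water",
]

REPORT_COLUMNS = [
    "name",
    "growth_form",
    "thsa",
    "biosurface",
    "pct_scale_sa",
    "theoretical_error_sa",
    "thv",
    "biomass",
    "pct_scale_v",
    "theoretical_error_v",
    "error_tvw",
]


def read_measurements_csv(path) -> list[ColonyMeasurements]:
    """Read a colony-measurements CSV (columns named as the field names)."""
    df = pd.read_csv(path)
    missing = [c for c in _RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurements CSV missing column(s): {missing}")
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for c in _RAW_COLUMNS:
            v = row[c]
            if c in ("name", "growth_form"):
                kwargs[c] = str(v)
            else:
                kwargs[c] = None if pd.isna(v) else float(v)
        out.append(ColonyMeasurements(**kwargs))
    return out


def write_measurements_csv(measurements, path) -> None:
    rows = []
    for m in measurements:
        rows.append({c: getattr(m, c) for c in _RAW_COLUMNS})
    pd.DataFrame(rows, columns=_RAW_COLUMNS).to_csv(path, index=False, float_format="%.2f")


def report_table(measurements) -> pd.DataFrame:
    """Derived-metric table, one row per colony, values at full precision.

    Column order follows the analysis suite (SA block then V block); round
    to 2 decimals at serialization for the printed-table layout.
    """
    rows = []
    for m in measurements:
        r = full_report(m)
        rows.append({c: getattr(r, c) for c in REPORT_COLUMNS})
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
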