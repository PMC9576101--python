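"""Agreement and robustness statistics for calibration validation.

Bland-Altman bias and 95% limits of agreement, method-comparison linear
regression, and per-sample coefficients of variation across repeated scan
conditions — the quantities used to compare internal calibration against a
reference phantom and against raw Hounsfield units.  Also a reader for the
per-sample supplementary densities workbook (long or wide layouts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AgreementReport",
    "CvTable",
    "RegressionResult",
    "SchemaError",
    "LOA_MULTIPLIER",
    "bland_altman",
    "cv_across_conditions",
    "regression_compare",
    "percent_difference",
    "load_supplementary_densities",
    "summarize_supplementary",
]

#: Normal-quantile multiplier behind "95% limits of agreement".
LOA_MULTIPLIER = 1.96

KNOWN_METHODS = ("HU", "internal", "sucrose_phantom", "HA_phantom")


class SchemaError(ValueError):
    """A workbook/table did not contain the expected sheets or columns."""


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept, "r_squared": self.r_squared}


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman agreement between two paired measurement series."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    regression: RegressionResult  # y-on-x method comparison
    bias_trend: RegressionResult | None  # difference vs pairwise mean

    @property
    def loa_halfwidth(self) -> float:
        return LOA_MULTIPLIER * self.sd_diff

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "loa_halfwidth": self.loa_halfwidth,
            "n": self.n,
            "regression": self.regression.to_dict(),
            "bias_trend": None if self.bias_trend is None else self.bias_trend.to_dict(),
        }


@dataclass(frozen=True)
class CvTable:
    """Per-sample coefficients of variation (%) across scan conditions."""

    per_sample: pd.Series  # index: sample id, values: CV %
    mean_cv: float  # %
    n_conditions: int


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("regression needs >= 2 points with varying x")
    if np.ptp(y) == 0:
        # scipy.linregress leaves r undefined for constant y; a flat response
        # is fit exactly by the horizontal line
        return RegressionResult(0.0, float(y.mean()), 1.0)
    res = sps.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept), float(res.rvalue**2))


def bland_altman(x: Sequence[float], y: Sequence[float]) -> AgreementReport:
    """Bland-Altman agreement of paired series ``x`` and ``y``.

    Differences are ``d = x - y``; bias is mean(d); limits of agreement are
    bias +/- 1.96 * SD(d) (sample SD, ddof=1).  The bias trend is the OLS of
    d on the pairwise means, flagging proportional error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"paired series must be 1-D and equal length, got {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("Bland-Altman needs n >= 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    means = (x + y) / 2.0
    try:
        trend = _ols(means, d)
    except ValueError:
        trend = None
    regression = _ols(x, y) if np.ptp(x) > 0 else RegressionResult(float("nan"), float("nan"), float("nan"))
    return AgreementReport(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        n=int(x.size),
        regression=regression,
        bias_trend=trend,
    )


def cv_across_conditions(values: pd.DataFrame | np.ndarray) -> CvTable:
    """Coefficient of variation per sample across repeated conditions.

    ``values`` has one row per sample and one column per scan condition.
    CV = 100 * SD / mean with sample SD (ddof=1); the mean CV is the
    arithmetic mean over samples.  Raises if any sample's mean is not
    positive (CV undefined — typical for raw HU series near or below zero,
    which is itself a reason HU is not a robust density surrogate).
    """
    frame = pd.DataFrame(values)
    if frame.shape[1] < 2:
        raise ValueError("need >= 2 conditions per sample to compute a CV")
    means = frame.mean(axis=1)
    if (means <= 0).any():
        bad = list(frame.index[means <= 0])
        raise ValueError(
            f"CV undefined for samples with non-positive mean: {bad}"
        )
    cv = 100.0 * frame.std(axis=1, ddof=1) / means
    return CvTable(per_sample=cv, mean_cv=float(cv.mean()), n_conditions=int(frame.shape[1]))


def regression_compare(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of ``y`` on ``x`` with coefficient of determination."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("regression comparison needs >= 3 paired values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: variance of x is zero")
    return _ols(x, y)


def percent_difference(reference: Sequence[float], other: Sequence[float]) -> float:
    """Mean percent difference of ``other`` from ``reference``.

    ``100 * mean((reference - other) / reference)`` over paired samples.
    """
    reference = np.asarray(reference, dtype=float)
    other = np.asarray(other, dtype=float)
    if reference.shape != other.shape:
        raise ValueError("paired series must have equal length")
    if np.any(reference == 0):
        raise ValueError("reference values must be nonzero")
    return float(100.0 * np.mean((reference - other) / reference))


# ---------------------------------------------------------------------------
# supplementary densities workbook
# ---------------------------------------------------------------------------

_LONG_COLUMNS = {"sample", "condition", "method", "value"}


def _normalise_method(name: str) -> str | None:
    key = str(name).strip().lower().replace(" ", "_").replace("-", "_")
    table = {
        "hu": "HU",
        "hounsfield": "HU",
        "native_hu": "HU",
        "internal": "internal",
        "internal_calibration": "internal",
        "sucrose": "sucrose_phantom",
        "sucrose_phantom": "sucrose_phantom",
        "sucrose_water_phantom": "sucrose_phantom",
        "phantom": "sucrose_phantom",
        "ha": "HA_phantom",
        "ha_phantom": "HA_phantom",
        "hydroxyapatite": "HA_phantom",
    }
    return table.get(key)


def load_supplementary_densities(path: str | Path) -> pd.DataFrame:
    """Load a per-sample density workbook into a tidy long table.

    Returns columns (sample, condition, method, value) with method one of
    {HU, internal, sucrose_phantom, HA_phantom} as available.  Two layouts
    are understood: a single long sheet with those columns, or one wide
    sheet per method (rows = samples, columns = scan conditions).  Anything
    else raises :class:`SchemaError` describing what was found.
    """
    path = Path(path)
    try:
        sheets = pd.read_excel(path, sheet_name=None)
    except ValueError as exc:
        raise SchemaError(f"could not read workbook {path}: {exc}") from exc
    if not sheets:
        raise SchemaError(f"workbook {path} contains no sheets")

    # layout 1: a long sheet
    for name, frame in sheets.items():
        cols = {str(c).strip().lower() for c in frame.columns}
        if _LONG_COLUMNS <= cols:
            frame = frame.rename(columns={c: str(c).strip().lower() for c in frame.columns})
            out = frame[["sample", "condition", "method", "value"]].copy()
            out["method"] = out["method"].map(lambda m: _normalise_method(m) or m)
            out["value"] = out["value"].astype(float)
            return out.reset_index(drop=True)

    # layout 2: one wide sheet per method
    records = []
    recognised = []
    for name, frame in sheets.items():
        method = _normalise_method(name)
        if method is None or frame.empty:
            continue
        recognised.append(name)
        frame = frame.set_index(frame.columns[0])
        for sample, row in frame.iterrows():
            for condition, value in row.items():
                if pd.isna(value):
                    continue
                records.append(
                    {
                        "sample": sample,
                        "condition": condition,
                        "method": method,
                        "value": float(value),
                    }
                )
    if not records:
        raise SchemaError(
            f"workbook {path} matches neither layout: no long sheet with columns "
            f"{sorted(_LONG_COLUMNS)} and no method-named wide sheets; found sheets "
            f"{list(sheets)}"
        )
    return pd.DataFrame.from_records(records)


def summarize_supplementary(
    table: pd.DataFrame,
    centre_condition: str | None = None,
) -> dict:
    """Headline statistics from a tidy supplementary density table.

    Computes, where methods allow: per-method mean CV across conditions;
    Bland-Altman bias internal vs sucrose phantom; percent difference between
    the phantom and internal methods; per-method mean value at
    ``centre_condition`` (or across all conditions if None); and R^2 between
    internal and phantom densities over all sample/condition pairs.
    """
    out: dict = {"methods": sorted(table["method"].unique())}
    wide = {
        m: g.pivot_table(index="sample", columns="condition", values="value")
        for m, g in table.groupby("method")
    }
    cvs = {}
    for m, frame in wide.items():
        try:
            cvs[m] = cv_across_conditions(frame).mean_cv
        except ValueError:
            cvs[m] = float("nan")
    out["mean_cv_percent"] = cvs

    if centre_condition is not None:
        sub = table[table["condition"] == centre_condition]
        out["mean_at_condition"] = {
            m: float(g["value"].mean()) for m, g in sub.groupby("method")
        }
    if {"internal", "sucrose_phantom"} <= set(wide):
        a = wide["internal"].sort_index()
        b = wide["sucrose_phantom"].sort_index()
        common_cols = [c for c in a.columns if c in b.columns]
        x = a[common_cols].to_numpy().ravel()
        y = b[common_cols].to_numpy().ravel()
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep], y[keep]
        report = bland_altman(x, y)
        out["bland_altman_internal_vs_phantom"] = report.to_dict()
        out["percent_difference_phantom_vs_internal"] = percent_difference(y, x)
        out["r_squared_internal_vs_phantom"] = regression_compare(y, x).r_squared
    return out
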