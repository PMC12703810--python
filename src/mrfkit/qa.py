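"""Validation statistics: ROI extraction, test-retest variation,
longitudinal CV, deviation from reference, Bland-Altman agreement, region
summaries and age-trend fits.

Test-retest variation for a set of paired measurements is

    Var = (1/N) * sum_i |test_i - retest_i| / ((test_i + retest_i) / 2) * 100

i.e. the mean absolute pairwise percent difference.  Bland-Altman uses the
signed per-pair percent difference with limits of agreement at the mean
difference +/- 1.96 sample standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from mrfkit.matching import ParameterMap

__all__ = [
    "ROISpec",
    "BlandAltmanResult",
    "AgeTrend",
    "MeasurementTable",
    "extract_roi_mean",
    "test_retest_variation",
    "coefficient_of_variation",
    "percent_deviation",
    "bland_altman",
    "region_summary",
    "age_trend",
    "qa_report",
]


@dataclass(frozen=True)
class ROISpec:
    """Circular ROI: 8 mm-diameter circle repeated over the listed slices.

    A pixel belongs to the ROI when its center (integer millimetre
    coordinates on the 1 mm grid) lies within the circle radius.
    """

    center_xy_mm: tuple
    slices: tuple
    diameter_mm: float = 8.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "slices", tuple(int(s) for s in self.slices))
        if self.diameter_mm <= 0:
            raise ValueError("ROI diameter must be positive")
        if len(self.slices) == 0:
            raise ValueError("ROI needs at least one slice")


def extract_roi_mean(
    pmap: ParameterMap, roi: ROISpec, metric: str = "t1_ms"
) -> tuple[float, int]:
    """Mean of ``metric`` over unmasked ROI voxels; returns ``(mean, count)``.

    Raises if every member voxel is masked out (e.g. a fat vial after
    low-T1 masking) or the ROI falls outside the volume.
    """
    volume = getattr(pmap, metric)
    nx, ny, nz = pmap.shape
    cx, cy = roi.center_xy_mm
    r = roi.diameter_mm / 2.0
    if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
        raise ValueError(f"ROI center {roi.center_xy_mm} outside the volume")
    for s in roi.slices:
        if not 0 <= s < nz:
            raise ValueError(f"ROI slice {s} outside the volume ({nz} slices)")

    x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r))
    xs = np.arange(max(x0, 0), min(x1, nx - 1) + 1)
    ys = np.arange(max(int(np.floor(cy - r)), 0), min(int(np.ceil(cy + r)), ny - 1) + 1)
    xg, yg = np.meshgrid(xs, ys, indexing="ij")
    member = (xg - cx) ** 2 + (yg - cy) ** 2 <= r**2
    if not member.any():
        raise ValueError("ROI contains no pixels")

    values = []
    for s in roi.slices:
        vals = volume[xg[member], yg[member], s]
        ok = pmap.mask[xg[member], yg[member], s]
        values.append(vals[ok])
    values = np.concatenate(values)
    if values.size == 0:
        raise ValueError(
            f"ROI at {roi.center_xy_mm} has no unmasked voxels (fully masked region)"
        )
    return float(values.mean()), int(values.size)


def test_retest_variation(pairs) -> float:
    """Mean absolute pairwise percent difference (see module docstring)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("pairs must be an (N, 2) array with N >= 1")
    if np.any(arr <= 0):
        raise ValueError("test/retest means must be positive")
    test, retest = arr[:, 0], arr[:, 1]
    return float(np.mean(np.abs(test - retest) / ((test + retest) / 2.0)) * 100.0)


def coefficient_of_variation(values) -> float:
    """Sample SD (n-1 denominator) over mean, in percent."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("mean is zero; CV undefined")
    return float(v.std(ddof=1) / m * 100.0)


def percent_deviation(measured: float, reference: float) -> float:
    """Signed percent deviation of ``measured`` from ``reference``."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return float((measured - reference) / reference * 100.0)


@dataclass(frozen=True)
class BlandAltmanResult:
    pair_means: np.ndarray
    diffs_pct: np.ndarray
    mean_diff_pct: float
    sd_diff_pct: float

    @property
    def loa_lower(self) -> float:
        return self.mean_diff_pct - 1.96 * self.sd_diff_pct

    @property
    def loa_upper(self) -> float:
        return self.mean_diff_pct + 1.96 * self.sd_diff_pct

    def to_dict(self) -> dict:
        return {
            "mean_diff_pct": self.mean_diff_pct,
            "sd_diff_pct": self.sd_diff_pct,
            "loa_lower_pct": self.loa_lower,
            "loa_upper_pct": self.loa_upper,
            "n_pairs": int(self.diffs_pct.size),
        }


def bland_altman(pairs) -> BlandAltmanResult:
    """Signed per-pair percent differences with 1.96-SD limits of agreement."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("pairs must be an (N, 2) array with N >= 2")
    test, retest = arr[:, 0], arr[:, 1]
    means = (test + retest) / 2.0
    if np.any(means == 0):
        raise ValueError("pair means must be nonzero")
    diffs = (test - retest) / means * 100.0
    return BlandAltmanResult(
        pair_means=means,
        diffs_pct=diffs,
        mean_diff_pct=float(diffs.mean()),
        sd_diff_pct=float(diffs.std(ddof=1)),
    )


def region_summary(pmap: ParameterMap, labels: np.ndarray) -> pd.DataFrame:
    """Per-label mean/SD of T1 and T2 over unmasked voxels plus volume.

    Volume is the unmasked voxel count times the voxel volume (0.005 cm3
    for 1 x 1 x 5 mm voxels).  Fully masked (empty) regions yield NaN
    statistics rather than raising.
    """
    labels = np.asarray(labels)
    if labels.shape != pmap.shape:
        raise ValueError(f"labels shape {labels.shape} != map shape {pmap.shape}")
    vox_cm3 = float(np.prod(pmap.voxel_size_mm)) / 1000.0
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = (labels == lab) & pmap.mask
        n = int(sel.sum())
        if n == 0:
            rows.append(
                dict(label=int(lab), n_voxels=0, volume_cm3=0.0,
                     t1_mean=np.nan, t1_sd=np.nan, t2_mean=np.nan, t2_sd=np.nan)
            )
            continue
        t1v = pmap.t1_ms[sel]
        t2v = pmap.t2_ms[sel]
        rows.append(
            dict(
                label=int(lab),
                n_voxels=n,
                volume_cm3=n * vox_cm3,
                t1_mean=float(t1v.mean()),
                t1_sd=float(t1v.std(ddof=1)) if n > 1 else 0.0,
                t2_mean=float(t2v.mean()),
                t2_sd=float(t2v.std(ddof=1)) if n > 1 else 0.0,
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AgeTrend:
    slope: float
    intercept: float
    r_squared: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
        }


def age_trend(ages, region_means) -> AgeTrend:
    """OLS linear fit of region means against age; two-sided slope p-value."""
    x = np.asarray(ages, dtype=float)
    y = np.asarray(region_means, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 (age, mean) points")
    if np.ptp(x) == 0:
        raise ValueError("ages must not all be equal")
    res = stats.linregress(x, y)
    return AgeTrend(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )


class MeasurementTable:
    """Long-format session/repeat/unit ROI means.

    Columns: ``session_day`` (int), ``repeat`` ('test'/'retest'), ``unit``
    (material or region name), ``metric`` ('t1_ms'/'t2_ms'), ``value``,
    optional ``temperature_C``.  (session_day, repeat, unit, metric) must
    be unique.
    """

    REQUIRED = ("session_day", "repeat", "unit", "metric", "value")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise ValueError(f"measurement table missing columns {sorted(missing)}")
        bad_rep = set(df["repeat"].unique()) - {"test", "retest"}
        if bad_rep:
            raise ValueError(f"repeat must be 'test' or 'retest', got {sorted(bad_rep)}")
        key = ["session_day", "repeat", "unit", "metric"]
        if df.duplicated(subset=key).any():
            raise ValueError("duplicate (session_day, repeat, unit, metric) rows")
        if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
            raise ValueError("all measurement values must be finite")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "MeasurementTable":
        return cls(pd.DataFrame.from_records(records))

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasurementTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def units(self):
        return sorted(self.df["unit"].unique())

    def metrics(self):
        return sorted(self.df["metric"].unique())

    def paired(self, unit: str, metric: str) -> np.ndarray:
        """(N, 2) test/retest pairs for one unit and metric, by session."""
        sub = self.df[(self.df["unit"] == unit) & (self.df["metric"] == metric)]
        piv = sub.pivot(index="session_day", columns="repeat", values="value")
        if "test" not in piv or "retest" not in piv:
            raise ValueError(f"unit {unit!r} metric {metric!r} lacks test/retest pairs")
        piv = piv.dropna(subset=["test", "retest"])
        return piv[["test", "retest"]].to_numpy(dtype=float)


def qa_report(
    table: MeasurementTable,
    reference: dict | None = None,
    cv_pooling: str = "session_mean",
) -> pd.DataFrame:
    """Per-(unit, metric) QA summary.

    Columns: test-retest variation %, longitudinal CV %, signed percent
    deviation of the study-mean value from the reference (when a
    ``reference[unit][metric]`` value is available), and Bland-Altman
    mean difference / limits of agreement.

    ``cv_pooling``: 'session_mean' computes the CV over per-session means
    of test and retest; 'all' pools every repeat as its own observation.
    """
    if cv_pooling not in ("session_mean", "all"):
        raise ValueError("cv_pooling must be 'session_mean' or 'all'")
    rows = []
    for unit in table.units():
        for metric in table.metrics():
            sub = table.df[(table.df["unit"] == unit) & (table.df["metric"] == metric)]
            if sub.empty:
                continue
            pairs = table.paired(unit, metric)
            variation = test_retest_variation(pairs)
            if cv_pooling == "session_mean":
                cv_values = pairs.mean(axis=1)
            else:
                cv_values = sub["value"].to_numpy(dtype=float)
            cv = coefficient_of_variation(cv_values) if cv_values.size >= 2 else np.nan
            ba = bland_altman(pairs) if pairs.shape[0] >= 2 else None
            ref_val = None
            if reference is not None:
                ref_val = reference.get(unit, {}).get(metric)
            rows.append(
                dict(
                    unit=unit,
                    metric=metric,
                    n_sessions=int(pairs.shape[0]),
                    test_retest_variation_pct=variation,
                    cv_pct=cv,
                    deviation_pct=(
                        percent_deviation(float(sub["value"].mean()), ref_val)
                        if ref_val is not None
                        else np.nan
                    ),
                    ba_mean_diff_pct=ba.mean_diff_pct if ba else np.nan,
                    ba_loa_lower_pct=ba.loa_lower if ba else np.nan,
                    ba_loa_upper_pct=ba.loa_upper if ba else np.nan,
                )
            )
    return pd.DataFrame(rows)
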