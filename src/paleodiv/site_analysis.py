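"""Per-record period slopes and leave-one-environment-out sensitivity.

Slopes: within each of three fixed 1,850-yr periods, each record's
transformed diversity series (log richness; logit evenness/turnover) is
regressed on age and the slope scaled to per-1,000-yr units. Sensitivity:
the trend and land-use analyses are re-run on median-over-resamples
diversity values with each depositional environment excluded in turn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import diversity as _div
from . import landuse as _landuse
from . import trends as _trends

#: period label -> (older bound, younger bound) in cal yr BP.
#: Common Era 1-1850 CE maps to 1,949-100 BP via BP = 1950 - CE.
PERIODS: Dict[str, Tuple[float, float]] = {
    "early_holocene": (11_700.0, 9_851.0),
    "mid_holocene": (6_725.0, 4_876.0),
    "common_era": (1_949.0, 100.0),
}

LOGIT_EPS = 1e-6
MIN_PERIOD_POINTS = 5

#: which value column feeds the slope transform per metric; turnover uses
#: raw dissimilarities since the adjusted values are not [0, 1] bounded.
_SLOPE_COLUMN = {
    "richness": "value",
    "evenness": "value",
    "turnover_bc": "raw",
    "turnover_jac": "raw",
}


def _logit(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, LOGIT_EPS, 1.0 - LOGIT_EPS)
    return np.log(x / (1.0 - x))


def transform_metric(metric: str, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if metric == "richness":
        return np.log(values)
    if metric in ("evenness", "turnover_bc", "turnover_jac"):
        return _logit(values)
    raise ValueError(f"no slope transform for metric {metric!r}")


def median_over_resamples(div_points: pd.DataFrame) -> pd.DataFrame:
    """Median per (record, metric, sample key) across resamples.

    Ages and intervals are summarized by their medians too, so the output
    looks like a single-resample diversity table.
    """
    keys = ["record_id", "region", "environment", "metric", "sample_key"]
    agg = (
        div_points.groupby(keys, sort=True, dropna=False)
        .agg(
            age=("age", "median"),
            interval=("interval", "median"),
            raw=("raw", "median"),
            value=("value", "median"),
            n_resamples=("resample_index", "nunique"),
        )
        .reset_index()
    )
    return agg


def period_slopes(
    points: pd.DataFrame,
    period: str,
    metric: str,
    min_points: int = MIN_PERIOD_POINTS,
) -> pd.DataFrame:
    """Per-record OLS slope of the transformed metric on age, x 1,000.

    Records with fewer than ``min_points`` in-period points are skipped.
    """
    old, young = PERIODS[period]
    sub = points[
        (points.metric == metric)
        & (points.age <= old)
        & (points.age >= young)
    ]
    col = _SLOPE_COLUMN[metric]
    rows = []
    for rid, grp in sub.groupby("record_id", sort=True):
        vals = grp[col].to_numpy(dtype=float)
        ages = grp.age.to_numpy(dtype=float)
        ok = np.isfinite(vals) & np.isfinite(ages)
        vals, ages = vals[ok], ages[ok]
        if metric == "richness":
            keep = vals >= 1
            vals, ages = vals[keep], ages[keep]
        if len(vals) < min_points:
            continue
        if np.ptp(ages) == 0:
            raise ValueError(
                f"record {rid!r}: all in-period ages identical; slope undefined"
            )
        t = transform_metric(metric, vals)
        slope = np.polyfit(ages, t, 1)[0]
        rows.append(
            {
                "record_id": rid,
                "region": grp.region.iloc[0],
                "environment": grp.environment.iloc[0],
                "period": period,
                "metric": metric,
                "slope_per_1000yr": float(slope * 1000.0),
                "n": int(len(vals)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "record_id", "region", "environment", "period", "metric",
            "slope_per_1000yr", "n",
        ],
    )


def summarize_slopes(slopes: pd.DataFrame) -> pd.DataFrame:
    """Boxplot-style five-number summaries per region x metric x period."""
    rows = []
    for (region, metric, period), grp in slopes.groupby(
        ["region", "metric", "period"], sort=True
    ):
        s = grp.slope_per_1000yr.to_numpy(dtype=float)
        q1, med, q3 = np.percentile(s, [25, 50, 75])
        iqr = q3 - q1
        rows.append(
            {
                "region": region,
                "metric": metric,
                "period": period,
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_low": float(q1 - 1.5 * iqr),
                "whisker_high": float(q3 + 1.5 * iqr),
                "frac_positive": float(np.mean(s > 0)),
                "n": int(len(s)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# leave-one-environment-out sensitivity


@dataclass
class SensitivityResult:
    excluded: str
    trend_curves: pd.DataFrame
    alcc_fits: pd.DataFrame
    skipped_regions: List[str]


def _subset_analysis(
    med: pd.DataFrame,
    alcc_series: Dict[str, "_landuse.ALCCSeries"],
    metrics: Sequence[str],
    k: int,
    age_grid: Optional[np.ndarray],
    excluded: str,
    all_regions: Optional[Sequence[str]] = None,
) -> SensitivityResult:
    skipped: List[str] = []
    trend_frames, fit_frames = [], []
    for metric in metrics:
        sub = med[med.metric == metric].copy()
        if metric in _div.TURNOVER_METRICS:
            # adjustment is recomputed on the subset, as in the full run
            sub = _div.adjust_turnover(sub, metric)
        counts = sub.groupby("region")["record_id"].nunique()
        good = sorted(counts[counts >= 2].index)
        skipped.extend(str(r) for r in counts[counts < 2].index)
        if all_regions is not None:
            skipped.extend(
                str(r) for r in all_regions if r not in set(counts.index)
            )
        sub = sub[sub.region.isin(good)]
        if sub.empty:
            continue
        points = sub[["record_id", "region", "age", "value"]].copy()
        fits, _model = _trends.fit_region_trends(
            points, k=k, age_grid=age_grid
        )
        trend_frames.append(_trends.region_fits_frame(fits, 0, metric))
        table = _landuse.join_alcc(
            sub[["record_id", "region", "age", "value"]].copy(), alcc_series
        )
        for region in good:
            rt = table[table.region == region]
            if rt.record_id.nunique() < 2 or len(rt) < 5:
                skipped.append(str(region))
                continue
            fit = _landuse.fit_alcc_model(rt, metric)
            fit_frames.append(_landuse.alcc_fit_frame([fit]))
    return SensitivityResult(
        excluded=excluded,
        trend_curves=(
            pd.concat(trend_frames, ignore_index=True)
            if trend_frames
            else pd.DataFrame()
        ),
        alcc_fits=(
            pd.concat(fit_frames, ignore_index=True)
            if fit_frames
            else pd.DataFrame()
        ),
        skipped_regions=sorted(set(skipped)),
    )


def sensitivity_loo(
    median_table: pd.DataFrame,
    alcc_series: Dict[str, "_landuse.ALCCSeries"],
    metrics: Sequence[str] = ("richness", "evenness", "turnover_bc"),
    k: int = 20,
    age_grid: Optional[np.ndarray] = None,
) -> Dict[str, SensitivityResult]:
    """Re-run trends and land-use fits with each environment left out.

    ``median_table`` is :func:`median_over_resamples` output. The key
    ``"__full__"`` holds the all-records analysis on the same medians.
    """
    envs = sorted(e for e in median_table.environment.dropna().unique())
    if len(envs) < 2:
        raise ValueError("need at least two depositional environments")
    all_regions = sorted(median_table.region.dropna().unique())
    out: Dict[str, SensitivityResult] = {}
    out["__full__"] = _subset_analysis(
        median_table, alcc_series, metrics, k, age_grid, excluded="",
        all_regions=all_regions,
    )
    for env in envs:
        sub = median_table[median_table.environment != env]
        out[env] = _subset_analysis(
            sub, alcc_series, metrics, k, age_grid, excluded=env,
            all_regions=all_regions,
        )
    return out
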