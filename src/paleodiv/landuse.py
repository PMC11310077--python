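"""Diversity vs anthropogenic land-cover change (ALCC) regressions.

Each diversity metric is regressed on square-root regional ALCC over
8,000-100 cal yr BP in a linear mixed model with record random intercepts
(ridge + REML). If the lag-1 residual autocorrelation within records
exceeds the white-noise 95% band, the model is refitted with AR(1)
within-record errors at rho = acf1 (quasi-differencing). Turnover,
evenness and heterogeneity are standardized before fitting and predictions
back-transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._penalized import Block, fit_reml
from .pollen_io import ALCCSeries
from .trends import Standardizer, standardize

ALCC_WINDOW = (8_000.0, 100.0)
STANDARDIZED_METRICS = (
    "turnover_bc",
    "turnover_jac",
    "evenness",
    "multi_bc",
    "multi_jac",
)


def join_alcc(
    points: pd.DataFrame,
    series,
    window: Tuple[float, float] = ALCC_WINDOW,
) -> pd.DataFrame:
    """Attach ALCC (and sqrt_ALCC) at round(age) to each diversity point.

    ``series`` is one :class:`ALCCSeries` or a dict region -> series.
    Points with age outside ``window`` (or outside the series years) are
    dropped.
    """
    old, young = window
    out = points[(points.age >= young) & (points.age <= old)].copy()
    if isinstance(series, ALCCSeries):
        series = {series.region: series}
    missing = sorted(set(out.region.unique()) - set(series))
    if missing:
        raise KeyError(f"regions missing from ALCC series: {missing}")
    alcc = np.full(len(out), np.nan)
    for region, grp in out.groupby("region", sort=False):
        alcc[out.index.get_indexer(grp.index)] = series[region].at(
            grp.age.to_numpy()
        )
    out["alcc"] = alcc
    out = out[np.isfinite(out.alcc)].copy()
    out["sqrt_alcc"] = np.sqrt(out.alcc)
    return out.reset_index(drop=True)


@dataclass
class ALCCFit:
    region: str
    metric: str
    slope: float
    slope_se: float
    intercept: float
    rho: float  # 0 when AR(1) correction not triggered
    acf1: float
    triggered: bool
    n: int
    n_records: int
    mean: float  # standardizer (identity for unstandardized metrics)
    sd: float
    alcc_range: Tuple[float, float]
    random_intercepts: bool = True

    def predict(self, alcc: np.ndarray) -> np.ndarray:
        """Back-transformed predictions at ALCC fractions (natural scale)."""
        alcc = np.asarray(alcc, dtype=float)
        eta = self.intercept + self.slope * np.sqrt(alcc)
        return eta * self.sd + self.mean


def lag1_autocorrelation(resid: np.ndarray, groups: np.ndarray) -> float:
    """Pooled lag-1 autocorrelation of residuals within groups."""
    num = 0.0
    den = float(np.sum(resid**2))
    if den == 0:
        return 0.0
    for g in pd.unique(groups):
        r = resid[groups == g]
        if len(r) >= 2:
            num += float(np.sum(r[:-1] * r[1:]))
    return num / den


def _ar1_transform(X: np.ndarray, y: np.ndarray, groups: np.ndarray, rho: float):
    """Within-group quasi-differencing (first row scaled by sqrt(1-rho^2))."""
    Xt = X.copy().astype(float)
    yt = y.copy().astype(float)
    c0 = np.sqrt(max(1.0 - rho**2, 1e-12))
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) == 0:
            continue
        Xt[idx[0]] *= c0
        yt[idx[0]] *= c0
        if len(idx) >= 2:
            Xt[idx[1:]] = X[idx[1:]] - rho * X[idx[:-1]]
            yt[idx[1:]] = y[idx[1:]] - rho * y[idx[:-1]]
    return Xt, yt


def _mixed_fit(X: np.ndarray, y: np.ndarray, rec_X: Optional[np.ndarray]):
    blocks = [Block(name="fixed", X=X, S=None)]
    if rec_X is not None:
        blocks.append(
            Block(name="records", X=rec_X, S=np.eye(rec_X.shape[1]),
                  rank=rec_X.shape[1])
        )
    try:
        return fit_reml(y, blocks), rec_X is not None
    except np.linalg.LinAlgError:
        warnings.warn(
            "random-intercept fit singular; falling back to fixed intercepts"
        )
        return fit_reml(y, [Block(name="fixed", X=X, S=None)]), False


def fit_alcc_model(
    table: pd.DataFrame,
    metric: str,
    do_standardize: Optional[bool] = None,
    random_intercepts: bool = True,
) -> ALCCFit:
    """Fit Diversity ~ sqrt_ALCC with record random intercepts and the
    two-stage AR(1) residual-autocorrelation correction.

    ``table`` is a single-region regression table from :func:`join_alcc`
    with columns record_id, region, age, value, sqrt_alcc.
    """
    sub = table[np.isfinite(table["value"])].copy()
    regions = sub.region.unique()
    if len(regions) != 1:
        raise ValueError("fit_alcc_model expects a single-region table")
    region = str(regions[0])
    if do_standardize is None:
        do_standardize = metric in STANDARDIZED_METRICS
    if do_standardize:
        sub, scalers = standardize(sub)
        scaler = scalers[region]
    else:
        sub["value_st"] = sub["value"].astype(float)
        scaler = Standardizer(0.0, 1.0)

    # time order within records: old -> young
    sub = sub.sort_values(["record_id", "age"], ascending=[True, False])
    sub = sub.reset_index(drop=True)
    y = sub.value_st.to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub)), sub.sqrt_alcc.to_numpy(dtype=float)])
    groups = sub.record_id.to_numpy()
    records = sorted(sub.record_id.unique())
    rec_X = None
    if random_intercepts and len(records) >= 2:
        idx = {r: j for j, r in enumerate(records)}
        rec_X = np.zeros((len(sub), len(records)))
        rec_X[np.arange(len(sub)), [idx[g] for g in groups]] = 1.0

    fit, used_re = _mixed_fit(X, y, rec_X)
    resid = y - fit.X @ fit.beta
    acf1 = lag1_autocorrelation(resid, groups)
    band = 1.96 / np.sqrt(len(y))
    triggered = bool(abs(acf1) > band)
    rho = 0.0
    if triggered:
        rho = float(np.clip(acf1, -0.99, 0.99))
        Xt, yt = _ar1_transform(
            np.hstack([X, rec_X]) if (used_re and rec_X is not None) else X,
            y,
            groups,
            rho,
        )
        if used_re and rec_X is not None:
            fit, used_re = _mixed_fit(Xt[:, :2], yt, Xt[:, 2:])
        else:
            fit, used_re = _mixed_fit(Xt, yt, None)

    beta = fit.coef("fixed")
    V = fit.cov("fixed")
    return ALCCFit(
        region=region,
        metric=metric,
        slope=float(beta[1]),
        slope_se=float(np.sqrt(max(V[1, 1], 0.0))),
        intercept=float(beta[0]),
        rho=rho,
        acf1=float(acf1),
        triggered=triggered,
        n=len(y),
        n_records=len(records),
        mean=scaler.mean,
        sd=scaler.sd,
        alcc_range=(float(sub.sqrt_alcc.min() ** 2), float(sub.sqrt_alcc.max() ** 2)),
        random_intercepts=used_re,
    )


def fit_heterogeneity_alcc(
    het: pd.DataFrame,
    series: ALCCSeries,
    metric: str = "multi_bc",
    window: Tuple[float, float] = ALCC_WINDOW,
) -> ALCCFit:
    """Bin-level ordinary regression of heterogeneity on sqrt-ALCC.

    One value per 500-yr bin (no record random effect); the ALCC regressor
    is the sqrt of the mean ALCC over the bin's years; the same lag-1 ACF
    rule applies on the bin sequence.
    """
    old, young = window
    sub = het[het.metric == metric].copy()
    regions = sub.region.unique()
    if len(regions) != 1:
        raise ValueError("expects a single-region heterogeneity table")
    region = str(regions[0])
    sub = sub[(sub.bin_start >= young - 1) & (sub.bin_end <= old + 1)]
    sub = sub.sort_values("bin_start", ascending=False).reset_index(drop=True)
    if len(sub) < 3:
        raise ValueError("too few heterogeneity bins for regression")
    alcc_means = []
    for row in sub.itertuples():
        years_mask = (series.years >= row.bin_start) & (series.years < row.bin_end)
        alcc_means.append(float(series.fraction[years_mask].mean()))
    sub["alcc"] = alcc_means
    sub["sqrt_alcc"] = np.sqrt(sub.alcc)
    sub["record_id"] = "bins"
    sub["age"] = 0.5 * (sub.bin_start + sub.bin_end)
    return fit_alcc_model(sub, metric, random_intercepts=False)


def alcc_fit_frame(fits: Sequence[ALCCFit], resample_index: int = 0) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": f.region,
                "metric": f.metric,
                "slope": f.slope,
                "slope_se": f.slope_se,
                "intercept": f.intercept,
                "rho": f.rho,
                "acf1": f.acf1,
                "n": f.n,
                "n_records": f.n_records,
                "resample_index": resample_index,
            }
            for f in fits
        ]
    )


def summarize_alcc_fits(
    fits: Sequence[ALCCFit], n_grid: int = 50
) -> pd.DataFrame:
    """Median / IQR prediction bands over the region's observed ALCC range.

    All fits must share one (region, metric); the x-axis is the ALCC
    fraction (back-transformed from sqrt).
    """
    if not fits:
        raise ValueError("no fits to summarize")
    keys = {(f.region, f.metric) for f in fits}
    if len(keys) != 1:
        raise ValueError("fits span multiple region/metric combinations")
    region, metric = keys.pop()
    lo = min(f.alcc_range[0] for f in fits)
    hi = max(f.alcc_range[1] for f in fits)
    grid = np.linspace(lo, hi, n_grid)
    preds = np.vstack([f.predict(grid) for f in fits])
    return pd.DataFrame(
        {
            "region": region,
            "metric": metric,
            "alcc": grid,
            "median": np.percentile(preds, 50, axis=0),
            "q25": np.percentile(preds, 25, axis=0),
            "q75": np.percentile(preds, 75, axis=0),
        }
    )
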