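"""Region-wise smooth trend models for diversity vs age.

Per resample and metric: standardize within region, fit a penalized-spline
model with one smooth per region plus record random intercepts (REML
smoothing selection), back-transform predictions, and compare against a
pooled single-smooth model by AIC. Resample cohorts are summarized as
pointwise median / interquartile curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._penalized import (
    Block,
    PenalizedFit,
    bspline_basis,
    centering_transform,
    difference_penalty,
    fit_reml,
    scaled_t_irls,
    smooth_wald_test,
)
from .errors import ZeroVarianceError

DEFAULT_K = 50
MODELLED_METRICS = ("turnover_bc", "turnover_jac", "richness", "evenness")


@dataclass
class Standardizer:
    mean: float
    sd: float

    def forward(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def standardize(
    df: pd.DataFrame, value_col: str = "value", by: str = "region"
) -> Tuple[pd.DataFrame, Dict[str, Standardizer]]:
    """Z-score ``value_col`` within each region (sd denominator n-1)."""
    out = df.copy()
    scalers: Dict[str, Standardizer] = {}
    out["value_st"] = np.nan
    for region, grp in df.groupby(by, sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        if not np.isfinite(sd) or sd == 0:
            raise ZeroVarianceError(
                f"region {region!r} has zero variance; cannot standardize"
            )
        s = Standardizer(float(np.mean(vals)), sd)
        scalers[str(region)] = s
        out.loc[grp.index, "value_st"] = s.forward(grp[value_col].to_numpy())
    return out, scalers


@dataclass
class RegionFit:
    """Fitted trend curve for one region on the natural scale."""

    region: str
    ages: np.ndarray
    fitted: np.ndarray  # NaN outside the region's observed age range
    se: np.ndarray
    edf: float
    loglik: float
    aic: float
    family: str
    p_value: float
    mean: float
    sd: float
    t_df: Optional[float] = None


@dataclass
class TrendModel:
    """Whole-model fit: penalized fit plus bookkeeping for comparisons."""

    fit: PenalizedFit
    regions: List[str]
    records: List[str]
    k_by_region: Dict[str, int]
    scalers: Dict[str, Standardizer]
    family: str
    n: int
    y_checksum: float


def _spline_block(ages_all, mask, k, domain, name):
    """Centered, difference-penalized spline block active on ``mask`` rows."""
    n = len(ages_all)
    B_sub, _ = bspline_basis(ages_all[mask], k, domain=domain)
    Z = centering_transform(B_sub)
    Bc = B_sub @ Z
    S = Z.T @ difference_penalty(k) @ Z
    X = np.zeros((n, Bc.shape[1]))
    X[mask] = Bc
    return Block(name=name, X=X, S=S, rank=k - 2), Z


def _record_block(record_ids: pd.Series, records: List[str]):
    n = len(record_ids)
    idx = {r: j for j, r in enumerate(records)}
    X = np.zeros((n, len(records)))
    X[np.arange(n), record_ids.map(idx).to_numpy()] = 1.0
    return Block(name="records", X=X, S=np.eye(len(records)), rank=len(records))


def _data_checksum(df: pd.DataFrame) -> float:
    """Checksum of the raw (pre-standardization) data for model comparison."""
    v = df["value"].to_numpy(dtype=float)
    a = df["age"].to_numpy(dtype=float)
    return float(np.sum(v) + np.sum(v**2) + np.sum(a) * 1e-6)


def _prepare(df: pd.DataFrame, do_standardize: bool):
    df = df[np.isfinite(df["value"])].reset_index(drop=True)
    if do_standardize:
        df, scalers = standardize(df)
    else:
        df = df.copy()
        df["value_st"] = df["value"].astype(float)
        scalers = {
            str(r): Standardizer(0.0, 1.0) for r in sorted(df.region.unique())
        }
    return df, scalers


def fit_region_trends(
    df: pd.DataFrame,
    k: int = DEFAULT_K,
    family: str = "gaussian",
    age_grid: Optional[np.ndarray] = None,
    do_standardize: bool = True,
) -> Tuple[Dict[str, RegionFit], TrendModel]:
    """Fit per-region penalized-spline trends with record random intercepts.

    ``df`` needs columns record_id, region, age, value. Returns one
    :class:`RegionFit` per region (natural scale) and the underlying
    :class:`TrendModel` for AIC comparison.
    """
    df, scalers = _prepare(df, do_standardize)
    regions = sorted(df.region.unique())
    records = sorted(df.record_id.unique())
    y = df.value_st.to_numpy(dtype=float)
    ages = df.age.to_numpy(dtype=float)

    blocks: List[Block] = []
    reg_X = np.zeros((len(df), len(regions)))
    for j, r in enumerate(regions):
        reg_X[(df.region == r).to_numpy(), j] = 1.0
    blocks.append(Block(name="region", X=reg_X, S=None))

    k_by_region: Dict[str, int] = {}
    smooth_info = {}
    for r in regions:
        mask = (df.region == r).to_numpy()
        uniq = np.unique(ages[mask])
        if len(uniq) < 5:
            raise ValueError(
                f"region {r!r} has only {len(uniq)} unique ages; "
                "too few for the spline basis — use a smaller k"
            )
        k_r = int(min(k, len(uniq)))
        k_by_region[r] = k_r
        domain = (float(uniq.min()), float(uniq.max()))
        blk, Z = _spline_block(ages, mask, k_r, domain, name=f"s({r})")
        blocks.append(blk)
        smooth_info[r] = (k_r, domain, Z)
    blocks.append(_record_block(df.record_id, records))

    if family == "scaled-t":
        fit, t_df, _scale = scaled_t_irls(y, blocks)
    else:
        fit = fit_reml(y, blocks)
        t_df = None

    model = TrendModel(
        fit=fit,
        regions=regions,
        records=records,
        k_by_region=k_by_region,
        scalers=scalers,
        family=family,
        n=len(y),
        y_checksum=_data_checksum(df),
    )

    if age_grid is None:
        age_grid = np.linspace(float(ages.min()), float(ages.max()), 100)
    age_grid = np.asarray(age_grid, dtype=float)

    region_fits: Dict[str, RegionFit] = {}
    reg_sl = fit.slices[0]
    for j, r in enumerate(regions):
        k_r, domain, Z = smooth_info[r]
        inside = (age_grid >= domain[0]) & (age_grid <= domain[1])
        fitted = np.full(len(age_grid), np.nan)
        se = np.full(len(age_grid), np.nan)
        if inside.any():
            B_g, _ = bspline_basis(age_grid[inside], k_r, domain=domain)
            Bc = B_g @ Z
            # design rows for [region intercept, smooth] prediction
            cols = list(range(reg_sl.start + j, reg_sl.start + j + 1))
            sl = next(
                s for b, s in zip(fit.blocks, fit.slices) if b.name == f"s({r})"
            )
            cols += list(range(sl.start, sl.stop))
            Xg = np.hstack([np.ones((inside.sum(), 1)), Bc])
            eta = Xg @ fit.beta[cols]
            V = fit.Vp[np.ix_(cols, cols)]
            var = np.einsum("ij,jk,ik->i", Xg, V, Xg)
            s = scalers[r]
            fitted[inside] = s.inverse(eta)
            se[inside] = np.sqrt(np.maximum(var, 0.0)) * s.sd
        _, _, p = smooth_wald_test(fit, f"s({r})")
        region_fits[r] = RegionFit(
            region=r,
            ages=age_grid,
            fitted=fitted,
            se=se,
            edf=fit.edf_by_block[f"s({r})"],
            loglik=fit.loglik,
            aic=fit.aic,
            family=family,
            p_value=p,
            mean=scalers[r].mean,
            sd=scalers[r].sd,
            t_df=t_df,
        )
    return region_fits, model


def fit_pooled_trend(
    df: pd.DataFrame,
    k: int = DEFAULT_K,
    family: str = "gaussian",
    do_standardize: bool = True,
) -> TrendModel:
    """Single-smooth model with no region terms (record intercepts kept)."""
    df, scalers = _prepare(df, do_standardize)
    records = sorted(df.record_id.unique())
    y = df.value_st.to_numpy(dtype=float)
    ages = df.age.to_numpy(dtype=float)
    uniq = np.unique(ages)
    if len(uniq) < 5:
        raise ValueError("too few unique ages for the spline basis")
    k_eff = int(min(k, len(uniq)))
    domain = (float(uniq.min()), float(uniq.max()))
    blocks = [Block(name="intercept", X=np.ones((len(df), 1)), S=None)]
    blk, _Z = _spline_block(
        ages, np.ones(len(df), dtype=bool), k_eff, domain, name="s(all)"
    )
    blocks.append(blk)
    blocks.append(_record_block(df.record_id, records))
    if family == "scaled-t":
        fit, _t_df, _scale = scaled_t_irls(y, blocks)
    else:
        fit = fit_reml(y, blocks)
    return TrendModel(
        fit=fit,
        regions=["all"],
        records=records,
        k_by_region={"all": k_eff},
        scalers=scalers,
        family=family,
        n=len(y),
        y_checksum=_data_checksum(df),
    )


def compare_aic(full: TrendModel, pooled: TrendModel) -> Tuple[float, bool]:
    """AIC_pooled - AIC_full; verdict region-structured iff >= 2."""
    if full.n != pooled.n or not np.isclose(full.y_checksum, pooled.y_checksum):
        raise ValueError("models were fitted to different data")
    delta = pooled.fit.aic - full.fit.aic
    return float(delta), bool(delta >= 2.0)


def region_fits_frame(
    region_fits: Dict[str, RegionFit], resample_index: int = 0, metric: str = ""
) -> pd.DataFrame:
    rows = []
    for r in sorted(region_fits):
        rf = region_fits[r]
        for a, f, s in zip(rf.ages, rf.fitted, rf.se):
            rows.append(
                {
                    "region": r,
                    "metric": metric,
                    "age": float(a),
                    "fitted": float(f),
                    "se": float(s),
                    "resample_index": resample_index,
                }
            )
    return pd.DataFrame(rows)


def summarize_resamples(curves: pd.DataFrame) -> pd.DataFrame:
    """Pointwise median / IQR of fitted curves across resamples.

    ``curves`` is the concatenation of :func:`region_fits_frame` outputs
    on a shared age grid.
    """
    def q(series, frac):
        vals = series.to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        return float(np.percentile(vals, frac)) if len(vals) else np.nan

    keys = [c for c in ("region", "metric", "age") if c in curves.columns]
    out = (
        curves.groupby(keys, sort=True)["fitted"]
        .agg(
            median=lambda s: q(s, 50),
            q25=lambda s: q(s, 25),
            q75=lambda s: q(s, 75),
        )
        .reset_index()
    )
    return out
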