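"""Within-record diversity metrics and multi-site heterogeneity.

Within-record metrics (per resample): interval-adjusted Bray-Curtis and
Jaccard turnover between stratigraphically successive samples, rarefied
richness and Pielou evenness. Between-record heterogeneity: multiple-site
Jaccard and an abundance-based multiple-site Bray-Curtis analogue in
500-year bins, with bootstrap record-count control.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pollen_io import HOLOCENE_WINDOW
from .resampling import RAREFY_N, ResampledDataset

TURNOVER_METRICS = ("turnover_bc", "turnover_jac")
SAMPLE_METRICS = ("richness", "evenness")
HET_METRICS = ("multi_bc", "multi_jac")
BIN_WIDTH = 500.0
MIN_REGION_RECORDS = 20


# ---------------------------------------------------------------------------
# pairwise metrics


def bray_curtis(x, y) -> float:
    """Sum |x-y| / sum (x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom <= 0:
        raise ValueError("Bray-Curtis undefined for two empty samples")
    return float(np.abs(x - y).sum() / denom)


def jaccard(x, y) -> float:
    """1 - |shared types| / |union of types| (incidence-based)."""
    x = np.asarray(x, dtype=float) > 0
    y = np.asarray(y, dtype=float) > 0
    union = (x | y).sum()
    if union == 0:
        raise ValueError("Jaccard undefined for two empty samples")
    return float(1.0 - (x & y).sum() / union)


def richness(counts) -> int:
    """Number of types in a 300-grain rarefied sample."""
    counts = np.asarray(counts)
    if counts.sum() != RAREFY_N:
        raise ValueError(f"richness requires a {RAREFY_N}-grain sample")
    return int(np.count_nonzero(counts))


def evenness(counts) -> float:
    """Pielou J = H / ln S; NaN (undefined) for single-type samples."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() != RAREFY_N:
        raise ValueError(f"evenness requires a {RAREFY_N}-grain sample")
    p = counts[counts > 0] / RAREFY_N
    s = len(p)
    if s <= 1:
        return float("nan")
    h = -np.sum(p * np.log(p))
    return float(h / np.log(s))


# ---------------------------------------------------------------------------
# turnover with time-interval adjustment


def turnover_pairs(dataset: ResampledDataset) -> pd.DataFrame:
    """Raw dissimilarities between successive in-window samples.

    One row per (record, consecutive pair, metric); the pair is keyed by
    the depths of its two samples so values can be aligned across
    resamples. The pair's age is the midpoint of the two sample ages.
    """
    rows = []
    for rid in sorted(dataset.records):
        rr = dataset.records[rid]
        if not rr.included:
            continue
        idx = np.flatnonzero(rr.in_window)
        for a, b in zip(idx, idx[1:]):
            x, y = rr.counts[a], rr.counts[b]
            interval = float(abs(rr.ages[b] - rr.ages[a]))
            key = f"{rr.depths[a]:g}|{rr.depths[b]:g}"
            age = float(0.5 * (rr.ages[a] + rr.ages[b]))
            common = {
                "record_id": rid,
                "region": rr.region,
                "environment": rr.environment,
                "sample_key": key,
                "age": age,
                "interval": interval,
                "resample_index": dataset.resample_index,
            }
            rows.append({**common, "metric": "turnover_bc", "raw": bray_curtis(x, y)})
            rows.append({**common, "metric": "turnover_jac", "raw": jaccard(x, y)})
    return pd.DataFrame(
        rows,
        columns=[
            "record_id", "region", "environment", "sample_key", "age",
            "interval", "resample_index", "metric", "raw",
        ],
    )


def expected_turnover_fit(raw: np.ndarray, interval: np.ndarray) -> Tuple[float, float]:
    """OLS of raw dissimilarity on log(interval + 1), pooled over pairs.

    Returns (intercept, slope); degenerate designs collapse to the global
    mean (slope 0).
    """
    x = np.log(np.asarray(interval, dtype=float) + 1.0)
    y = np.asarray(raw, dtype=float)
    if len(y) == 0:
        return 0.0, 0.0
    if len(y) < 2 or np.ptp(x) == 0:
        return float(y.mean()), 0.0
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[0]), float(beta[1])


def adjust_turnover(pairs: pd.DataFrame, metric: Optional[str] = None) -> pd.DataFrame:
    """Subtract the expected (interval-dependent) turnover from raw values.

    The expectation is fitted pooled over all pairs in the dataset, per
    metric. Adds ``expected`` and ``value`` (= adjusted) columns.
    """
    if pairs.empty:
        out = pairs.copy()
        out["expected"] = pd.Series(dtype=float)
        out["value"] = pd.Series(dtype=float)
        return out
    metrics = [metric] if metric else sorted(pairs.metric.unique())
    chunks = []
    for m in metrics:
        sub = pairs[pairs.metric == m].copy()
        a, b = expected_turnover_fit(sub.raw.to_numpy(), sub.interval.to_numpy())
        sub["expected"] = a + b * np.log(sub.interval.to_numpy() + 1.0)
        sub["value"] = sub.raw - sub.expected
        chunks.append(sub)
    return pd.concat(chunks, ignore_index=True)


# ---------------------------------------------------------------------------
# per-resample diversity table


def diversity_table(dataset: ResampledDataset) -> pd.DataFrame:
    """Long-form per-record diversity values for one resample.

    Columns: record_id, region, environment, sample_key, age, interval,
    resample_index, metric, raw, expected, value. For richness/evenness
    ``raw == value``; for turnover ``value`` is interval-adjusted.
    """
    frames = [adjust_turnover(turnover_pairs(dataset))]
    rows = []
    for rid in sorted(dataset.records):
        rr = dataset.records[rid]
        if not rr.included:
            continue
        for i in np.flatnonzero(rr.in_window):
            common = {
                "record_id": rid,
                "region": rr.region,
                "environment": rr.environment,
                "sample_key": f"{rr.depths[i]:g}",
                "age": float(rr.ages[i]),
                "interval": np.nan,
                "resample_index": dataset.resample_index,
            }
            s = richness(rr.counts[i])
            j = evenness(rr.counts[i])
            rows.append(
                {**common, "metric": "richness", "raw": float(s),
                 "expected": np.nan, "value": float(s)}
            )
            rows.append(
                {**common, "metric": "evenness", "raw": j, "expected": np.nan,
                 "value": j}
            )
    frames.append(pd.DataFrame(rows, columns=frames[0].columns))
    out = pd.concat(frames, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# multiple-site heterogeneity


def multi_site_jaccard(incidence: np.ndarray) -> float:
    """Multiple-site Jaccard dissimilarity of a sites x taxa table.

    ``sum_pairs(b_ij + b_ji) / (A + sum_pairs(b_ij + b_ji))`` with
    ``A = sum_i S_i - S_total`` (reduces to pairwise Jaccard for 2 sites).
    """
    inc = np.asarray(incidence) > 0
    n = inc.shape[0]
    if n < 2:
        raise ValueError("need at least two sites")
    a_comp = inc.sum() - (inc.any(axis=0)).sum()
    shared = inc.astype(int) @ inc.astype(int).T  # pairwise shared counts
    s = inc.sum(axis=1)
    b_sum = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            b_sum += (s[i] - shared[i, j]) + (s[j] - shared[i, j])
    if a_comp + b_sum == 0:
        return 0.0
    return float(b_sum / (a_comp + b_sum))


def multi_site_bray_curtis(abund: np.ndarray) -> float:
    """Abundance-based multiple-site Bray-Curtis analogue.

    ``sum_pairs sum_k |x_ki - x_kj| / (2A + same)`` with the multiple-site
    shared component ``A = sum_k (sum_i x_ki - max_i x_ki)``; reduces to
    pairwise Bray-Curtis for 2 sites.
    """
    x = np.asarray(abund, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two sites")
    a_comp = float(x.sum() - x.max(axis=0).sum())
    b_sum = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            b_sum += np.abs(x[i] - x[j]).sum()
    if 2 * a_comp + b_sum == 0:
        return 0.0
    return float(b_sum / (2 * a_comp + b_sum))


def time_bins(window: Tuple[float, float] = HOLOCENE_WINDOW) -> List[Tuple[float, float]]:
    """500-yr bins anchored at the young window edge; terminal bin closes
    the window exactly."""
    old, young = window
    edges = np.arange(young, old, BIN_WIDTH)
    bins = [(float(e), float(min(e + BIN_WIDTH, old))) for e in edges]
    return bins


def _bin_tables(dataset: ResampledDataset, regions: Sequence[str], window):
    """region -> bin -> {record_id: count row} using the sample nearest the
    bin centre for each record present in the bin."""
    bins = time_bins(window)
    out: Dict[str, Dict[int, Dict[str, np.ndarray]]] = {
        reg: {k: {} for k in range(len(bins))} for reg in regions
    }
    taxa_union: Dict[str, List[str]] = {}
    for reg in regions:
        taxa = sorted(
            {
                t
                for rr in dataset.records.values()
                if rr.included and rr.region == reg
                for t in rr.taxa
            }
        )
        taxa_union[reg] = taxa
    for rid in sorted(dataset.records):
        rr = dataset.records[rid]
        if not rr.included or rr.region not in out:
            continue
        tindex = {t: i for i, t in enumerate(taxa_union[rr.region])}
        idx = np.flatnonzero(rr.in_window)
        ages = rr.ages[idx]
        for k, (lo, hi) in enumerate(bins):
            centre = 0.5 * (lo + hi)
            inbin = idx[(ages >= lo) & (ages < hi)]
            if len(inbin) == 0:
                continue
            best = inbin[np.argmin(np.abs(rr.ages[inbin] - centre))]
            row = np.zeros(len(tindex), dtype=np.int64)
            for t, j in tindex.items():
                ti = rr.taxa.index(t) if t in rr.taxa else -1
                if ti >= 0:
                    row[j] = rr.counts[best, ti]
            out[rr.region][k][rid] = row
    return bins, out


def heterogeneity(
    dataset: ResampledDataset,
    bin_width: float = BIN_WIDTH,
    B: int = 100,
    seed: int = 0,
    min_region_records: int = MIN_REGION_RECORDS,
    window: Tuple[float, float] = HOLOCENE_WINDOW,
) -> pd.DataFrame:
    """Binned multi-site dissimilarity with bootstrap record-count control.

    Per region (>= ``min_region_records`` records) and 500-yr bin, one
    sample per record (nearest bin centre); ``n_min`` is the minimum
    record count over all bins x regions; each bin is subsampled to
    ``n_min`` records ``B`` times without replacement and the multi-site
    metrics averaged. Bins with fewer than 2 records are skipped.
    """
    if bin_width != BIN_WIDTH:
        raise ValueError("bin width is fixed at 500 yr")
    counts_by_region: Dict[str, int] = {}
    for rr in dataset.records.values():
        if rr.included and rr.region is not None:
            counts_by_region[rr.region] = counts_by_region.get(rr.region, 0) + 1
    regions = sorted(
        r for r, c in counts_by_region.items() if c >= min_region_records
    )
    if not regions:
        return pd.DataFrame(
            columns=["region", "bin_start", "bin_end", "metric", "value",
                     "n_records", "resample_index"]
        )
    bins, tables = _bin_tables(dataset, regions, window)
    occupied = [
        (reg, k)
        for reg in regions
        for k in range(len(bins))
        if len(tables[reg][k]) >= 2
    ]
    if not occupied:
        return pd.DataFrame(
            columns=["region", "bin_start", "bin_end", "metric", "value",
                     "n_records", "resample_index"]
        )
    n_min = min(len(tables[reg][k]) for reg, k in occupied)
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(dataset.resample_index,))
    )
    rows = []
    for reg, k in occupied:
        table = tables[reg][k]
        rids = sorted(table)
        mat = np.vstack([table[r] for r in rids])
        vals_bc, vals_jac = [], []
        if len(rids) == n_min:
            vals_bc.append(multi_site_bray_curtis(mat))
            vals_jac.append(multi_site_jaccard(mat))
        else:
            for _ in range(B):
                pick = rng.choice(len(rids), size=n_min, replace=False)
                sub = mat[np.sort(pick)]
                vals_bc.append(multi_site_bray_curtis(sub))
                vals_jac.append(multi_site_jaccard(sub))
        lo, hi = bins[k]
        for metric, vals in (("multi_bc", vals_bc), ("multi_jac", vals_jac)):
            rows.append(
                {
                    "region": reg,
                    "bin_start": lo,
                    "bin_end": hi,
                    "metric": metric,
                    "value": float(np.mean(vals)),
                    "n_records": len(rids),
                    "resample_index": dataset.resample_index,
                }
            )
    return pd.DataFrame(rows)
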