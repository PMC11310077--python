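"""Joint rarefaction / age-uncertainty resampling.

Each of ``R`` resamples pairs a fresh 300-grain rarefaction of every sample
with one Monte-Carlo age draw per record, applies the Holocene window and
re-checks the five-in-window-samples rule. Seeds are derived from a master
seed by counter-based spawning keyed on (resample index, record index), so
the stream is reproducible independently of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chronology import AgeDraw, CurveSpec, _ControlSampler, curve_for, MAX_EXTRAPOLATION, _interp_with_extrapolation
from .pollen_io import HOLOCENE_WINDOW, PollenRecord

RAREFY_N = 300

_AGES_STREAM = 0
_RAREFY_STREAM = 1


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


def rarefy_sample(counts, n: int = RAREFY_N, seed=None, rng=None):
    """Draw ``n`` grains without replacement (multivariate hypergeometric).

    Accepts a mapping taxon -> count or an integer array; returns the same
    type. A total below ``n`` is an error — the filter should have removed
    such samples.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(counts, Mapping):
        names = list(counts.keys())
        vec = np.array([counts[k] for k in names], dtype=np.int64)
    else:
        names = None
        vec = np.asarray(counts, dtype=np.int64)
    total = int(vec.sum())
    if total < n:
        raise ValueError(f"cannot rarefy {total} grains to {n}")
    if total == n:
        out = vec.copy()
    else:
        out = rng.multivariate_hypergeometric(vec, n)
    if names is None:
        return out
    return {k: int(v) for k, v in zip(names, out)}


@dataclass
class RecordResample:
    """One record's state within one resample."""

    record_id: str
    region: Optional[str]
    environment: Optional[str]
    depths: np.ndarray
    ages: np.ndarray  # NaN = age-undefined
    taxa: List[str]
    counts: np.ndarray  # (n_samples, n_taxa); every row sums to RAREFY_N
    in_window: np.ndarray  # bool mask
    included: bool


@dataclass
class ResampledDataset:
    resample_index: int
    master_seed: int
    records: Dict[str, RecordResample]

    @property
    def realized_records(self) -> int:
        return sum(1 for r in self.records.values() if r.included)

    @property
    def realized_samples(self) -> int:
        return int(
            sum(r.in_window.sum() for r in self.records.values() if r.included)
        )


def build_resample(
    records: Sequence[PollenRecord],
    age_draws: Mapping[str, AgeDraw],
    resample_index: int,
    master_seed: int,
    window: Tuple[float, float] = HOLOCENE_WINDOW,
    min_samples: int = 5,
) -> ResampledDataset:
    """Assemble one joint resample from records and their age draws.

    Samples that are age-undefined or outside the window are dropped;
    records left with fewer than ``min_samples`` in-window samples are
    flagged excluded for this resample only.
    """
    old, young = window
    out: Dict[str, RecordResample] = {}
    for idx, rec in enumerate(sorted(records, key=lambda r: r.record_id)):
        if rec.record_id not in age_draws:
            raise KeyError(f"missing age draw for record {rec.record_id!r}")
        draw = age_draws[rec.record_id]
        ages = np.asarray(draw.ages, dtype=float)
        if len(ages) != len(rec.samples):
            raise ValueError(
                f"age draw length mismatch for record {rec.record_id!r}"
            )
        taxa = sorted({t for s in rec.samples for t in s.counts})
        tindex = {t: j for j, t in enumerate(taxa)}
        rng = _rng(master_seed, resample_index, idx, _RAREFY_STREAM)
        counts = np.zeros((len(rec.samples), len(taxa)), dtype=np.int64)
        for i, s in enumerate(rec.samples):
            vec = np.zeros(len(taxa), dtype=np.int64)
            for t, c in s.counts.items():
                vec[tindex[t]] = c
            counts[i] = rarefy_sample(vec, RAREFY_N, rng=rng)
        in_window = np.isfinite(ages) & (ages >= young) & (ages <= old)
        out[rec.record_id] = RecordResample(
            record_id=rec.record_id,
            region=rec.region,
            environment=rec.depositional_environment,
            depths=rec.depths,
            ages=ages,
            taxa=taxa,
            counts=counts,
            in_window=in_window,
            included=bool(in_window.sum() >= min_samples),
        )
    return ResampledDataset(
        resample_index=resample_index, master_seed=master_seed, records=out
    )


class _AgeModelCache:
    """Per-record calibrated-posterior samplers, built once for all R."""

    def __init__(self, records: Sequence[PollenRecord], curves: CurveSpec):
        self.samplers = {}
        for rec in records:
            curve = curve_for(rec, curves)
            self.samplers[rec.record_id] = _ControlSampler(rec.controls, curve)

    def draw(self, rec: PollenRecord, rng: np.random.Generator) -> AgeDraw:
        sampler = self.samplers[rec.record_id]
        ctrl = sampler.draw_monotone(1, rng)[0]
        depths = rec.depths
        ages = _interp_with_extrapolation(depths, sampler.depths, ctrl)
        over = np.zeros(len(depths), dtype=bool)
        top, bot = sampler.depths[0], sampler.depths[-1]
        over |= (depths < top) & (np.abs(ages - ctrl[0]) > MAX_EXTRAPOLATION)
        over |= (depths > bot) & (np.abs(ages - ctrl[-1]) > MAX_EXTRAPOLATION)
        ages[over] = np.nan
        return AgeDraw(record_id=rec.record_id, ages=ages, draw_index=-1)


def run_resamples(
    records: Sequence[PollenRecord],
    curves: CurveSpec,
    R: int,
    master_seed: int,
    window: Tuple[float, float] = HOLOCENE_WINDOW,
) -> Iterator[ResampledDataset]:
    """Stream ``R`` joint resamples of filtered records."""
    if R < 1:
        raise ValueError("R must be >= 1")
    records = sorted(records, key=lambda r: r.record_id)
    cache = _AgeModelCache(records, curves)
    for r in range(R):
        draws = {}
        for idx, rec in enumerate(records):
            rng = _rng(master_seed, r, idx, _AGES_STREAM)
            draws[rec.record_id] = cache.draw(rec, rng)
        yield build_resample(records, draws, r, master_seed, window=window)


def realized_summary(datasets: Sequence[ResampledDataset]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "resample_index": d.resample_index,
                "records": d.realized_records,
                "samples": d.realized_samples,
            }
            for d in datasets
        ]
    )


def dataset_to_frame(dataset: ResampledDataset) -> pd.DataFrame:
    """Long-form dump of one resample (cache format for the CLI)."""
    rows = []
    for rid in sorted(dataset.records):
        rr = dataset.records[rid]
        for i in range(len(rr.depths)):
            for j, t in enumerate(rr.taxa):
                c = rr.counts[i, j]
                if c > 0:
                    rows.append(
                        (
                            rid,
                            rr.region,
                            rr.environment,
                            rr.depths[i],
                            rr.ages[i],
                            bool(rr.in_window[i]),
                            rr.included,
                            t,
                            int(c),
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "record_id",
            "region",
            "environment",
            "depth",
            "age",
            "in_window",
            "included",
            "taxon",
            "count",
        ],
    )


def dataset_from_frame(df: pd.DataFrame, resample_index: int, master_seed: int = -1) -> ResampledDataset:
    records = {}
    for rid, grp in df.groupby("record_id", sort=True):
        depths = np.array(sorted(grp.depth.unique()))
        taxa = sorted(grp.taxon.unique())
        tindex = {t: j for j, t in enumerate(taxa)}
        dindex = {d: i for i, d in enumerate(depths)}
        counts = np.zeros((len(depths), len(taxa)), dtype=np.int64)
        ages = np.full(len(depths), np.nan)
        inw = np.zeros(len(depths), dtype=bool)
        for row in grp.itertuples():
            i = dindex[row.depth]
            counts[i, tindex[row.taxon]] = row.count
            ages[i] = row.age
            inw[i] = row.in_window
        first = grp.iloc[0]
        records[str(rid)] = RecordResample(
            record_id=str(rid),
            region=first.region,
            environment=first.environment,
            depths=depths,
            ages=ages,
            taxa=taxa,
            counts=counts,
            in_window=inw,
            included=bool(first.included),
        )
    return ResampledDataset(
        resample_index=resample_index, master_seed=master_seed, records=records
    )
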