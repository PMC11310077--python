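"""Radiocarbon calibration, Monte-Carlo age-depth draws and record filters.

The age-depth sampler draws one calendar age per chronological control from
its calibrated posterior, conditioned on superposition (ages non-decreasing
with depth) by joint rejection sampling, then interpolates piecewise
linearly to sample depths. Samples more than 3,000 years of extrapolation
beyond the outermost control are left age-undefined (NaN).

This is deliberately simpler than a compound Poisson-gamma sediment
accumulation model: the downstream pipeline consumes only individual
monotone draws honouring the calibrated uncertainties, which this sampler
provides.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import CalibrationRangeError, MonotoneSamplingError
from .pollen_io import ChronControl, HOLOCENE_WINDOW, PollenRecord, PollenSample

MAX_EXTRAPOLATION = 3_000.0  # yr beyond the outermost control
MAX_CONTROL_GAP = 3_000.0  # yr between consecutive controls
MIN_CONTROLS = 3
MIN_SAMPLES = 5
MIN_GRAINS = 300


@dataclass
class CalibrationCurve:
    """Calibration curve on a strictly increasing calendar-age grid."""

    cal_age: np.ndarray
    c14_age: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.cal_age = np.asarray(self.cal_age, dtype=float)
        self.c14_age = np.asarray(self.c14_age, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(self.cal_age) <= 0):
            raise ValueError("cal_age grid must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("curve sigma must be positive")

    def c14_at(self, cal) -> np.ndarray:
        return np.interp(cal, self.cal_age, self.c14_age)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"cal_age": self.cal_age, "c14_age": self.c14_age, "sigma": self.sigma}
        ).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CalibrationCurve":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            df.cal_age.to_numpy(), df.c14_age.to_numpy(), df.sigma.to_numpy()
        )


@dataclass
class AgeDraw:
    """One Monte-Carlo realization of sample ages for a record."""

    record_id: str
    ages: np.ndarray  # cal yr BP per sample depth; NaN = age-undefined
    draw_index: int


@dataclass
class FilterReport:
    record_id: str
    kept: bool
    reason: Optional[str] = None  # rejection reason when not kept
    depth_interval: Optional[Tuple[float, float]] = None
    n_controls: int = 0
    n_samples: int = 0


CurveSpec = Union[CalibrationCurve, Dict[str, CalibrationCurve], None]


def curve_for(record: PollenRecord, curves: CurveSpec) -> Optional[CalibrationCurve]:
    """Resolve the calibration curve for a record.

    A dict keyed ``{"north", "south"}`` selects by site latitude sign
    (lat >= 0 -> northern curve); a single curve applies everywhere.
    """
    if curves is None or isinstance(curves, CalibrationCurve):
        return curves
    return curves["north" if record.lat >= 0 else "south"]


def calibrate(
    control: ChronControl, curve: Optional[CalibrationCurve]
) -> Tuple[np.ndarray, np.ndarray]:
    """Posterior density over calendar age on the curve grid, summing to 1.

    Radiocarbon: density proportional to
    Normal(measured; curve_mean(cal), sqrt(error^2 + curve_sigma(cal)^2)).
    Calendar controls return a Gaussian density directly.
    """
    if control.kind == "calendar":
        if curve is not None:
            grid = curve.cal_age
        else:
            half = max(5 * control.error, 50.0)
            grid = np.linspace(control.age - half, control.age + half, 501)
        if control.error == 0:
            dens = np.zeros_like(grid)
            dens[np.argmin(np.abs(grid - control.age))] = 1.0
            return grid, dens
        dens = np.exp(-0.5 * ((grid - control.age) / control.error) ** 2)
    else:
        if curve is None:
            raise ValueError("radiocarbon control requires a calibration curve")
        grid = curve.cal_age
        sd = np.sqrt(control.error**2 + curve.sigma**2)
        lo = curve.c14_age.min() - 4 * sd.max()
        hi = curve.c14_age.max() + 4 * sd.max()
        if not (lo <= control.age <= hi):
            raise CalibrationRangeError(
                f"radiocarbon age {control.age} outside curve support "
                f"[{curve.c14_age.min():.0f}, {curve.c14_age.max():.0f}]"
            )
        z = (control.age - curve.c14_age) / sd
        dens = np.exp(-0.5 * z**2) / sd
    total = dens.sum()
    if total <= 0:
        raise CalibrationRangeError(
            f"calibrated posterior for age {control.age} has zero mass"
        )
    return grid, dens / total


def posterior_median(control: ChronControl, curve: Optional[CalibrationCurve]) -> float:
    """Median of the calibrated posterior (calendar controls: measured age)."""
    if control.kind == "calendar":
        return float(control.age)
    if curve is None:
        return float(control.age)  # proxy when no curve is supplied
    grid, dens = calibrate(control, curve)
    cdf = np.cumsum(dens)
    return float(np.interp(0.5, cdf, grid))


class _ControlSampler:
    """Precomputed per-control inverse-CDF samplers for one record."""

    def __init__(self, controls: Sequence[ChronControl], curve: Optional[CalibrationCurve]):
        self.controls = sorted(controls, key=lambda c: c.depth)
        self.depths = np.array([c.depth for c in self.controls])
        self._samplers = []
        for c in self.controls:
            if c.kind == "calendar":
                self._samplers.append(("normal", float(c.age), float(c.error)))
            else:
                grid, dens = calibrate(c, curve)
                cdf = np.cumsum(dens)
                step = np.gradient(grid)
                self._samplers.append(("grid", grid, cdf, step))

    def _draw_one(self, i: int, n: int, rng: np.random.Generator) -> np.ndarray:
        s = self._samplers[i]
        if s[0] == "normal":
            _, mu, sd = s
            return np.full(n, mu) if sd == 0 else rng.normal(mu, sd, size=n)
        _, grid, cdf, step = s
        u = rng.random(n)
        idx = np.searchsorted(cdf, u * cdf[-1])
        idx = np.clip(idx, 0, len(grid) - 1)
        # treat the discrete posterior as a histogram: jitter within cells
        return grid[idx] + (rng.random(n) - 0.5) * step[idx]

    def draw_monotone(
        self, n: int, rng: np.random.Generator, max_retries: int = 100_000
    ) -> np.ndarray:
        """(n, m) control ages, non-decreasing along depth order.

        Joint rejection sampling with a retry cap; remaining draws fall
        back to sorting the proposed ages (always terminates).
        """
        m = len(self.controls)
        out = np.empty((n, m))
        filled = 0
        attempts = 0
        while filled < n and attempts < max_retries:
            batch = min(max(4 * (n - filled), 64), max_retries - attempts)
            prop = np.column_stack([self._draw_one(i, batch, rng) for i in range(m)])
            ok = np.all(np.diff(prop, axis=1) >= 0, axis=1)
            good = prop[ok]
            take = min(len(good), n - filled)
            out[filled : filled + take] = good[:take]
            filled += take
            attempts += batch
        if filled < n:
            # fallback: sort proposals into depth order
            prop = np.column_stack(
                [self._draw_one(i, n - filled, rng) for i in range(m)]
            )
            out[filled:] = np.sort(prop, axis=1)
        return out


def _interp_with_extrapolation(
    depths: np.ndarray, cdepths: np.ndarray, cages: np.ndarray
) -> np.ndarray:
    """Piecewise-linear interpolation, end-segment slopes beyond controls."""
    ages = np.interp(depths, cdepths, cages)
    if len(cdepths) >= 2:
        above = depths < cdepths[0]
        below = depths > cdepths[-1]
        if above.any():
            s = (cages[1] - cages[0]) / (cdepths[1] - cdepths[0])
            ages[above] = cages[0] + s * (depths[above] - cdepths[0])
        if below.any():
            s = (cages[-1] - cages[-2]) / (cdepths[-1] - cdepths[-2])
            ages[below] = cages[-1] + s * (depths[below] - cdepths[-1])
    return ages


def sample_age_models(
    record: PollenRecord,
    curve: Optional[CalibrationCurve],
    n_draws: int,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    max_extrapolation: float = MAX_EXTRAPOLATION,
) -> List[AgeDraw]:
    """Monte-Carlo age draws at the record's sample depths.

    Each draw samples control ages jointly (monotone in depth) and
    interpolates. Ages requiring more than ``max_extrapolation`` years of
    extrapolation beyond the outermost control are NaN.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(record.controls) < 2:
        raise MonotoneSamplingError(
            f"record {record.record_id!r} has fewer than two controls"
        )
    sampler = _ControlSampler(record.controls, curve)
    ctrl_ages = sampler.draw_monotone(n_draws, rng)
    depths = record.depths
    draws = []
    for d in range(n_draws):
        ages = _interp_with_extrapolation(depths, sampler.depths, ctrl_ages[d])
        over = np.zeros(len(depths), dtype=bool)
        top, bot = sampler.depths[0], sampler.depths[-1]
        over |= (depths < top) & (np.abs(ages - ctrl_ages[d][0]) > max_extrapolation)
        over |= (depths > bot) & (np.abs(ages - ctrl_ages[d][-1]) > max_extrapolation)
        ages = ages.copy()
        ages[over] = np.nan
        finite = ages[np.isfinite(ages)]
        assert np.all(np.diff(finite) >= -1e-9), "age draw violates superposition"
        draws.append(AgeDraw(record_id=record.record_id, ages=ages, draw_index=d))
    return draws


# ---------------------------------------------------------------------------
# inclusion filter


def _median_age_model(controls, curve):
    ctrls = sorted(controls, key=lambda c: c.depth)
    depths = np.array([c.depth for c in ctrls])
    meds = np.array([posterior_median(c, curve) for c in ctrls])
    return depths, meds


def filter_records(
    records: Sequence[PollenRecord],
    curves: CurveSpec = None,
    window: Tuple[float, float] = HOLOCENE_WINDOW,
    max_gap: float = MAX_CONTROL_GAP,
    min_controls: int = MIN_CONTROLS,
    min_samples: int = MIN_SAMPLES,
    min_grains: int = MIN_GRAINS,
) -> Tuple[List[PollenRecord], List[FilterReport]]:
    """Apply the record-inclusion criteria; keep best qualifying sections.

    A record (or section) qualifies when it has >= ``min_controls``
    in-window controls, no consecutive control gap above ``max_gap`` years
    and >= ``min_samples`` in-window samples of >= ``min_grains`` grains.
    When several sections of one record qualify, the one with the most
    controls is kept (ties: longer time span, then older). Rejections are
    reported, never raised.
    """
    old, young = window
    kept_records: List[PollenRecord] = []
    reports: List[FilterReport] = []

    for rec in records:
        curve = curve_for(rec, curves)
        holo = []
        for c in rec.controls:
            med = posterior_median(c, curve)
            if young <= med <= old:
                holo.append((c, med))
        holo.sort(key=lambda t: t[0].depth)

        if len(holo) < min_controls:
            reports.append(
                FilterReport(rec.record_id, False, "too-few-controls",
                             n_controls=len(holo), n_samples=len(rec.samples))
            )
            continue

        # split controls into runs with gaps <= max_gap (in median age)
        runs: List[List[Tuple[ChronControl, float]]] = [[holo[0]]]
        for prev, cur in zip(holo, holo[1:]):
            if abs(cur[1] - prev[1]) > max_gap:
                runs.append([cur])
            else:
                runs[-1].append(cur)
        candidates = [r for r in runs if len(r) >= min_controls]
        if not candidates:
            reports.append(
                FilterReport(rec.record_id, False, "control-gap",
                             n_controls=len(holo), n_samples=len(rec.samples))
            )
            continue

        best = None
        best_key = None
        best_counts = (0, 0)  # (max n_holo, max n_valid) over candidates
        for run in candidates:
            ctrls = [c for c, _ in run]
            depths = np.array([c.depth for c in ctrls])
            meds = np.array([m for _, m in run])
            other_spans = [
                (min(c.depth for c, _ in r), max(c.depth for c, _ in r))
                for r in runs
                if r is not run
            ]
            eligible = []
            valid = []
            for s in rec.samples:
                in_other = any(lo <= s.depth <= hi for lo, hi in other_spans)
                if in_other:
                    continue
                age = float(
                    _interp_with_extrapolation(
                        np.array([s.depth]), depths, meds
                    )[0]
                )
                if s.depth < depths[0] and abs(age - meds[0]) > MAX_EXTRAPOLATION:
                    continue
                if s.depth > depths[-1] and abs(age - meds[-1]) > MAX_EXTRAPOLATION:
                    continue
                if not (young <= age <= old):
                    continue
                eligible.append(s)
                if s.grain_total() >= min_grains:
                    valid.append(s)
            best_counts = (
                max(best_counts[0], len(eligible)),
                max(best_counts[1], len(valid)),
            )
            if len(valid) >= min_samples:
                key = (len(ctrls), float(meds.max() - meds.min()), float(meds.max()))
                if best_key is None or key > best_key:
                    best_key = key
                    best = (ctrls, valid)

        if best is None:
            reason = (
                "too-few-samples" if best_counts[0] < min_samples else "low-count-samples"
            )
            reports.append(
                FilterReport(rec.record_id, False, reason,
                             n_controls=len(holo), n_samples=len(rec.samples))
            )
            continue

        ctrls, samples = best
        samples = sorted(samples, key=lambda s: s.depth)
        trimmed = replace(rec, samples=samples, controls=list(ctrls))
        kept_records.append(trimmed)
        reports.append(
            FilterReport(
                rec.record_id,
                True,
                depth_interval=(samples[0].depth, samples[-1].depth),
                n_controls=len(ctrls),
                n_samples=len(samples),
            )
        )
    return kept_records, reports


def filter_report_frame(reports: Sequence[FilterReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "kept": r.kept,
                "reason": r.reason or "",
                "depth_min": r.depth_interval[0] if r.depth_interval else np.nan,
                "depth_max": r.depth_interval[1] if r.depth_interval else np.nan,
                "n_controls": r.n_controls,
                "n_samples": r.n_samples,
            }
            for r in reports
        ]
    )
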