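"""Synthetic pollen worlds with known generative truth.

A "world" bundles everything the pipeline consumes: multi-record pollen
counts with heterogeneous grain totals, radiocarbon-style chronological
controls, calibration curves, a harmonization table, a rectangle region
map, gridded regional land-use (ALCC) fractions — plus a
:class:`GenerativeTruth` object retaining the true trend functions,
record intercepts and signed ALCC effects for parameter-recovery tests.

Generative model
----------------
Each region has a taxon pool arranged on a ring. The community at age ``a``
is a window of ``S(a)`` taxa around a drifting centre, with exponentially
decaying ranked abundances. Regional ALCC enters causally:

* richness effect — widens/narrows the active window,
* evenness effect — flattens/steepens the abundance decay,
* turnover effect — speeds/slows the drift of the window centre.

Record-level random intercepts (plus a fixed offset per depositional
environment) tilt the decay rate only, so environments shift intercepts
but not trends.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import pollen_io
from .chronology import CalibrationCurve
from .errors import InvalidConfigError
from .pollen_io import (
    ALCCSeries,
    ChronControl,
    HarmonizationTable,
    PollenRecord,
    PollenSample,
    RegionMap,
    RegionRect,
)

ALCC_YEARS = np.arange(8000, 99, -1, dtype=float)  # annual, 8,000 -> 100 BP
METRICS = ("richness", "evenness", "turnover")


@dataclass
class ALCCParams:
    """Logistic land-use trajectory: fraction vs age (cal yr BP)."""

    onset: float  # midpoint age, cal yr BP
    rate: float  # per yr
    plateau: float  # asymptotic fraction in [0, 1]


@dataclass
class DiversityEffects:
    """Signed effect sizes of ALCC on the three within-record metrics."""

    richness: float
    evenness: float
    turnover: float


_DEFAULT_EFFECTS = [
    DiversityEffects(0.8, 0.7, 1.0),
    DiversityEffects(-0.5, -0.5, 0.8),
    DiversityEffects(0.6, 0.4, 1.2),
]

_DEFAULT_ENVIRONMENTS = ("lake", "bog", "fen", "mire", "marsh", "hollow")


@dataclass
class WorldConfig:
    n_regions: int = 3
    records_per_region: int = 10
    taxon_pool_size: int = 40
    time_span: Tuple[float, float] = (11_700.0, 100.0)
    alcc_params: Optional[List[ALCCParams]] = None
    diversity_effects: Optional[List[DiversityEffects]] = None
    noise_sd: float = 0.0
    seed: int = 0
    # generator knobs
    intercept_sd: float = 0.15
    env_intercept_sd: float = 0.10
    base_richness: int = 18
    base_concentration: float = 3.0
    base_turnover_rate: float = 1.5e-3  # ring positions per yr
    samples_per_record: Tuple[int, int] = (18, 36)
    grain_total_range: Tuple[int, int] = (300, 5000)
    controls_per_record: Tuple[int, int] = (4, 8)
    control_error_range: Tuple[float, float] = (30.0, 80.0)
    environments: Tuple[str, ...] = _DEFAULT_ENVIRONMENTS
    #: ranges the record's youngest/oldest true sample ages are drawn from;
    #: spans close to the analysis window create per-resample record churn
    record_span_young: Tuple[float, float] = (300.0, 1200.0)
    record_span_old: Tuple[float, float] = (9800.0, 11_200.0)
    #: when True the shallowest control is a precise calendar date, pinning
    #: the young end of each age model (set False to let it float)
    top_control_calendar: bool = True

    def resolved_alcc_params(self) -> List[ALCCParams]:
        if self.alcc_params is not None:
            return list(self.alcc_params)
        return [
            ALCCParams(
                onset=5500.0 - 900.0 * (i % 6),
                rate=0.0015 + 0.0004 * (i % 4),
                plateau=0.45 + 0.10 * (i % 3),
            )
            for i in range(self.n_regions)
        ]

    def resolved_effects(self) -> List[DiversityEffects]:
        if self.diversity_effects is not None:
            return list(self.diversity_effects)
        return [
            _DEFAULT_EFFECTS[i % len(_DEFAULT_EFFECTS)] for i in range(self.n_regions)
        ]

    def validate(self) -> List[str]:
        bad = []
        if self.n_regions < 1:
            bad.append("n_regions")
        if self.records_per_region < 0:
            bad.append("records_per_region")
        if self.taxon_pool_size < 8:
            bad.append("taxon_pool_size")
        if not self.time_span[0] > self.time_span[1]:
            bad.append("time_span")
        if self.noise_sd < 0:
            bad.append("noise_sd")
        if self.intercept_sd < 0:
            bad.append("intercept_sd")
        for p in self.resolved_alcc_params():
            if not (0.0 <= p.plateau <= 1.0):
                bad.append("alcc_params.plateau")
                break
        if len(self.resolved_alcc_params()) < self.n_regions:
            bad.append("alcc_params")
        if len(self.resolved_effects()) < self.n_regions:
            bad.append("diversity_effects")
        return bad


def logistic_alcc(params: ALCCParams, ages) -> np.ndarray:
    """Logistic land-use fraction at ``ages`` (cal yr BP).

    ``plateau / (1 + exp(-rate * (onset - age)))``: rises toward the
    present (smaller age) for positive rates.
    """
    if not (0.0 <= params.plateau <= 1.0):
        raise InvalidConfigError(
            "ALCC plateau must lie in [0, 1]", fields=["plateau"]
        )
    ages = np.asarray(ages, dtype=float)
    z = np.clip(params.rate * (params.onset - ages), -700, 700)
    return params.plateau / (1.0 + np.exp(-z))


def generate_alcc_series(
    params: ALCCParams, region: str = "region", years: Optional[np.ndarray] = None
) -> ALCCSeries:
    years = ALCC_YEARS if years is None else np.asarray(years, dtype=float)
    return ALCCSeries(region=region, years=years, fraction=logistic_alcc(params, years))


class GenerativeTruth:
    """True generative functions and latent values of one world."""

    def __init__(self, config: WorldConfig):
        self.config = config
        self.regions = [f"region_{i}" for i in range(config.n_regions)]
        self.alcc_params = dict(zip(self.regions, config.resolved_alcc_params()))
        self.effects = dict(zip(self.regions, config.resolved_effects()))
        self.record_intercepts: Dict[str, float] = {}
        self.record_true_ages: Dict[str, List[float]] = {}
        offsets = (
            config.env_intercept_sd
            * np.linspace(-1.0, 1.0, max(len(config.environments), 2))
        )
        self.env_offsets = dict(zip(config.environments, offsets.tolist()))
        # precompute drift-centre cumulative integrals per region
        self._drift_grid = np.arange(config.time_span[0], -1.0, -10.0)
        self._drift_cum = {}
        for r in self.regions:
            rate = self.turnover_rate(r, self._drift_grid)
            self._drift_cum[r] = np.concatenate(
                [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * 10.0)]
            )[: len(self._drift_grid)]

    # -- latent functions ---------------------------------------------------

    def alcc(self, region: str, ages) -> np.ndarray:
        return logistic_alcc(self.alcc_params[region], ages)

    def turnover_rate(self, region: str, ages) -> np.ndarray:
        """Ring-drift speed (positions per yr), the true turnover driver."""
        eff = self.effects[region].turnover
        base = self.config.base_turnover_rate
        return base * np.maximum(0.0, 1.0 + eff * self.alcc(region, ages))

    def _centre(self, region: str, age: float) -> float:
        # cumulative drift from the oldest age toward the present
        return float(
            np.interp(-age, -self._drift_grid, self._drift_cum[region])
        )

    def active_richness(self, region: str, age: float) -> int:
        cfg = self.config
        a = float(self.alcc(region, age))
        s = round(cfg.base_richness * (1.0 + self.effects[region].richness * a))
        return int(np.clip(s, 3, cfg.taxon_pool_size))

    def composition(
        self, region: str, age: float, intercept: float = 0.0
    ) -> Tuple[List[str], np.ndarray]:
        """(taxon names, probabilities) of the community at ``age``."""
        cfg = self.config
        P = cfg.taxon_pool_size
        a = float(self.alcc(region, age))
        lam = cfg.base_concentration * np.exp(
            intercept - self.effects[region].evenness * a
        )
        S = self.active_richness(region, age)
        c = self._centre(region, age) % P
        pos = np.arange(P, dtype=float)
        d = np.abs(pos - c)
        d = np.minimum(d, P - d)  # circular distance
        order = np.lexsort((pos, d))
        active = np.sort(order[:S])
        w = np.exp(-2.0 * lam * d[active] / S)
        p = w / w.sum()
        names = [f"{region}_tax{i:02d}" for i in active]
        return names, p

    # -- true trend functions ----------------------------------------------

    def expected_richness(self, region: str, age: float, n: int = 300) -> float:
        """Expected rarefied richness of a multinomial ``n``-grain draw."""
        _, p = self.composition(region, age)
        return float(np.sum(1.0 - (1.0 - p) ** n))

    def expected_evenness(self, region: str, age: float) -> float:
        _, p = self.composition(region, age)
        h = -np.sum(p * np.log(p))
        return float(h / np.log(len(p)))

    def trend(self, region: str, metric: str, ages) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        if metric == "richness":
            return np.array([self.expected_richness(region, a) for a in ages])
        if metric == "evenness":
            return np.array([self.expected_evenness(region, a) for a in ages])
        if metric == "turnover":
            return self.turnover_rate(region, ages)
        raise ValueError(f"unknown metric {metric!r}")

    def true_slope_sign(self, region: str, metric: str) -> float:
        return float(np.sign(getattr(self.effects[region], metric)))

    # -- (de)serialization ---------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "config": _config_to_dict(self.config),
            "record_intercepts": self.record_intercepts,
            "record_true_ages": self.record_true_ages,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GenerativeTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        truth = cls(_config_from_dict(payload["config"]))
        truth.record_intercepts = dict(payload["record_intercepts"])
        truth.record_true_ages = {
            k: list(v) for k, v in payload["record_true_ages"].items()
        }
        return truth


def _config_to_dict(cfg: WorldConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if cfg.alcc_params is not None:
        d["alcc_params"] = [dataclasses.asdict(p) for p in cfg.alcc_params]
    if cfg.diversity_effects is not None:
        d["diversity_effects"] = [
            dataclasses.asdict(e) for e in cfg.diversity_effects
        ]
    return d


def _config_from_dict(d: dict) -> WorldConfig:
    d = dict(d)
    if d.get("alcc_params") is not None:
        d["alcc_params"] = [ALCCParams(**p) for p in d["alcc_params"]]
    if d.get("diversity_effects") is not None:
        d["diversity_effects"] = [DiversityEffects(**e) for e in d["diversity_effects"]]
    for key in ("time_span", "samples_per_record", "grain_total_range",
                "controls_per_record", "control_error_range", "environments"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return WorldConfig(**d)


# ---------------------------------------------------------------------------
# world assembly


def _default_region_map(regions: Sequence[str]) -> RegionMap:
    rects = []
    for i, label in enumerate(regions):
        lat_min = -45.0 + 22.0 * (i % 6)
        rects.append(
            RegionRect(
                label=label,
                lat_min=lat_min,
                lat_max=lat_min + 18.0,
                lon_min=10.0 * i,
                lon_max=10.0 * i + 8.0,
            )
        )
    return RegionMap(rects)


def _default_curves() -> Dict[str, CalibrationCurve]:
    cal = np.arange(0.0, 13_501.0, 5.0)
    north = CalibrationCurve(
        cal_age=cal,
        c14_age=cal + 40.0 * np.sin(cal / 300.0),
        sigma=12.0 + 0.0008 * cal,
    )
    south = CalibrationCurve(
        cal_age=cal,
        c14_age=cal + 35.0 * np.sin(cal / 280.0 + 1.0),
        sigma=14.0 + 0.0008 * cal,
    )
    return {"north": north, "south": south}


def _harmonization_table(truth: GenerativeTruth) -> HarmonizationTable:
    mapping = {}
    for region in truth.regions:
        for i in range(truth.config.taxon_pool_size):
            name = f"{region}_tax{i:02d}"
            mapping[name] = (name, pollen_io.TERRESTRIAL)
            mapping[f"{name}-type"] = (name, pollen_io.TERRESTRIAL)
        mapping[f"Spore_{region}"] = (f"Spore_{region}", "spore")
        mapping[f"Aquatic_{region}"] = (f"Aquatic_{region}", "aquatic")
    return HarmonizationTable(mapping)


def generate_record(
    region: str,
    truth: GenerativeTruth,
    seed,
    record_id: Optional[str] = None,
    environment: Optional[str] = None,
    defective: Optional[str] = None,
    rect: Optional[RegionRect] = None,
) -> PollenRecord:
    """Generate one pollen record from a region's generative truth.

    ``defective`` makes the record violate exactly one inclusion criterion:
    ``"too-few-controls"``, ``"control-gap"``, ``"too-few-samples"`` or
    ``"low-count-samples"``.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    if record_id is None:
        record_id = f"{region}_rec{rng.integers(10**6):06d}"
    if environment is None:
        environment = str(
            cfg.environments[int(rng.integers(len(cfg.environments)))]
        )
    intercept = float(
        rng.normal(0.0, cfg.intercept_sd) + truth.env_offsets[environment]
    )

    if defective == "too-few-samples":
        n = 4
    else:
        lo, hi = cfg.samples_per_record
        n = int(rng.integers(lo, hi + 1))

    old = float(rng.uniform(*cfg.record_span_old))
    young = float(rng.uniform(*cfg.record_span_young))
    base = np.linspace(young, old, n)
    spacing = (old - young) / max(n - 1, 1)
    ages = np.sort(base + rng.uniform(-0.3, 0.3, size=n) * spacing)
    ages = np.clip(ages, 150.0, 11_600.0)
    ages = np.maximum.accumulate(ages + np.arange(n) * 1e-6)

    depths = 5.0 + np.cumsum(rng.uniform(2.0, 8.0, size=n))

    lo_g, hi_g = cfg.grain_total_range
    totals = rng.integers(lo_g, hi_g + 1, size=n)
    if defective == "low-count-samples":
        n = 5
        ages, depths, totals = ages[:5], depths[:5], totals[:5]
        totals[2] = 250

    samples = []
    for i in range(n):
        names, p = truth.composition(region, float(ages[i]), intercept)
        if cfg.noise_sd > 0:
            alpha = p / (cfg.noise_sd**2)
            p = rng.dirichlet(alpha)
        counts = rng.multinomial(int(totals[i]), p)
        alias_suffix = "" if i % 2 == 0 else "-type"
        raw = {
            f"{name}{alias_suffix}": int(c)
            for name, c in zip(names, counts)
            if c > 0
        }
        raw[f"Spore_{region}"] = int(rng.poisson(4.0) + 1)
        if rng.random() < 0.3:
            raw[f"Aquatic_{region}"] = int(rng.poisson(3.0) + 1)
        samples.append(PollenSample(depth=float(depths[i]), counts=raw))

    # chronological controls along the record's true age-depth relation
    if defective == "too-few-controls":
        ctrl_ages = np.array([young + 200.0, old - 200.0])
    elif defective == "control-gap":
        ctrl_ages = np.array([young + 100.0, young + 1600.0, young + 5100.0])
        ctrl_ages = np.clip(ctrl_ages, young, old)
    else:
        lo_c, hi_c = cfg.controls_per_record
        k = int(rng.integers(lo_c, hi_c + 1))
        k = max(k, int(np.ceil((old - young) / 2500.0)) + 1)
        k = min(k, 15)
        ctrl_ages = np.linspace(young + 30.0, old - 30.0, k)
        ctrl_ages = ctrl_ages + rng.uniform(-80.0, 80.0, size=k)
        ctrl_ages = np.sort(np.clip(ctrl_ages, young, old))

    lat_lo, lat_hi = (rect.lat_min, rect.lat_max) if rect else (0.0, 10.0)
    lon_lo, lon_hi = (rect.lon_min, rect.lon_max) if rect else (0.0, 10.0)
    lat = float(rng.uniform(lat_lo + 0.5, lat_hi - 0.5))
    lon = float(rng.uniform(lon_lo + 0.5, lon_hi - 0.5))
    curves = _default_curves()
    curve = curves["north" if lat >= 0 else "south"]

    controls = []
    for j, ta in enumerate(ctrl_ages):
        depth = float(np.interp(ta, ages, depths))
        if j == 0 and cfg.top_control_calendar:
            err = float(rng.uniform(10.0, 30.0))
            controls.append(
                ChronControl(depth=depth, age=float(ta), error=err, kind="calendar")
            )
        else:
            err = float(rng.uniform(*cfg.control_error_range))
            measured = float(curve.c14_at(ta) + rng.normal(0.0, err))
            controls.append(
                ChronControl(depth=depth, age=measured, error=err, kind="radiocarbon")
            )
    controls.sort(key=lambda c: c.depth)

    truth.record_intercepts[record_id] = intercept
    truth.record_true_ages[record_id] = [float(a) for a in ages]
    return PollenRecord(
        record_id=record_id,
        lat=lat,
        lon=lon,
        samples=samples,
        controls=controls,
        continent=region,
        biome=region,
        depositional_environment=environment,
    )


@dataclass
class World:
    config: WorldConfig
    records: List[PollenRecord]
    curves: Dict[str, CalibrationCurve]
    harmonization: HarmonizationTable
    region_map: RegionMap
    alcc_grid: pd.DataFrame
    alcc_series: Dict[str, ALCCSeries]
    truth: GenerativeTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pollen_io.write_records(
            self.records,
            outdir / "counts.csv",
            outdir / "controls.csv",
            outdir / "metadata.json",
        )
        self.harmonization.to_csv(outdir / "harmonization.csv")
        self.region_map.to_csv(outdir / "region_map.csv")
        for name, curve in sorted(self.curves.items()):
            curve.to_csv(outdir / f"curve_{name}.csv")
        pollen_io.write_alcc_grid(self.alcc_grid, outdir / "alcc_grid.csv")
        pollen_io.write_alcc_series(
            list(self.alcc_series.values()), outdir / "alcc_series.csv"
        )
        self.truth.to_json(outdir / "truth.json")

    @classmethod
    def read(cls, outdir) -> "World":
        outdir = Path(outdir)
        truth = GenerativeTruth.from_json(outdir / "truth.json")
        curves = {
            p.stem.removeprefix("curve_"): CalibrationCurve.read_csv(p)
            for p in sorted(outdir.glob("curve_*.csv"))
        }
        return cls(
            config=truth.config,
            records=pollen_io.read_records(
                outdir / "counts.csv",
                outdir / "controls.csv",
                outdir / "metadata.json",
            ),
            curves=curves,
            harmonization=HarmonizationTable.read_csv(outdir / "harmonization.csv"),
            region_map=RegionMap.read_csv(outdir / "region_map.csv"),
            alcc_grid=pollen_io.read_alcc_grid(outdir / "alcc_grid.csv"),
            alcc_series=pollen_io.read_alcc_series(outdir / "alcc_series.csv"),
            truth=truth,
        )


def generate_world(config: WorldConfig) -> World:
    """Generate a complete, mutually consistent synthetic world."""
    bad = config.validate()
    if bad:
        raise InvalidConfigError(
            f"invalid world config; offending fields: {', '.join(bad)}", fields=bad
        )
    truth = GenerativeTruth(config)
    region_map = _default_region_map(truth.regions)
    curves = _default_curves()
    harmonization = _harmonization_table(truth)

    records = []
    for r, region in enumerate(truth.regions):
        rect = region_map.rects[r]
        for j in range(config.records_per_region):
            seed = np.random.SeedSequence(config.seed, spawn_key=(1, r, j))
            records.append(
                generate_record(
                    region,
                    truth,
                    seed,
                    record_id=f"{region}_rec{j:03d}",
                    rect=rect,
                )
            )

    series = {
        region: generate_alcc_series(truth.alcc_params[region], region=region)
        for region in truth.regions
    }
    rows = []
    for r, region in enumerate(truth.regions):
        rect = region_map.rects[r]
        lats = [rect.lat_min + 4.0, rect.lat_min + 9.0]
        lons = [rect.lon_min + 1.5, rect.lon_min + 4.5]
        s = series[region]
        for lat in lats:
            for lon in lons:
                rows.append(
                    pd.DataFrame(
                        {
                            "year": s.years,
                            "lat": lat,
                            "lon": lon,
                            "fraction": s.fraction,
                        }
                    )
                )
    grid = pd.concat(rows, ignore_index=True)

    return World(
        config=config,
        records=records,
        curves=curves,
        harmonization=harmonization,
        region_map=region_map,
        alcc_grid=grid,
        alcc_series=series,
        truth=truth,
    )


def generate_defective_suite(
    config: Optional[WorldConfig] = None, seed: int = 0
) -> Dict[str, PollenRecord]:
    """One record per inclusion criterion, each violating exactly that one.

    Keys: ``too-few-controls``, ``control-gap``, ``too-few-samples``,
    ``low-count-samples`` and ``compliant``.
    """
    config = config or WorldConfig(n_regions=1, records_per_region=0)
    truth = GenerativeTruth(config)
    region = truth.regions[0]
    out = {}
    for i, kind in enumerate(
        ["too-few-controls", "control-gap", "too-few-samples", "low-count-samples"]
    ):
        out[kind] = generate_record(
            region,
            truth,
            np.random.SeedSequence(seed, spawn_key=(9, i)),
            record_id=f"defective_{kind}",
            defective=kind,
        )
    out["compliant"] = generate_record(
        region,
        truth,
        np.random.SeedSequence(seed, spawn_key=(9, 99)),
        record_id="compliant",
    )
    return out
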