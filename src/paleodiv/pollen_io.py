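"""Pollen data model and tabular I/O.

Records are exchanged as three flat files: a long-form counts CSV
(``record_id, depth, raw_taxon, count``), a chronological-controls CSV
(``record_id, depth, age, error, kind``) and a JSON file of per-record site
metadata. Ages are calendar years before present (cal yr BP, present =
1950 CE; larger = older), depths are centimetres increasing downcore.

This module also hosts the three dataset-level operations that precede any
analysis: taxonomic harmonization, region assignment from an axis-aligned
rectangle map, and reduction of a gridded land-use product to regional
annual mean series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import (
    InvalidRegionMapError,
    PaleodivError,
    UnassignedRegionError,
    UnmappedTaxonError,
)

TERRESTRIAL = "terrestrial-pollen"
GROUPS = (TERRESTRIAL, "spore", "aquatic", "other")

#: analysis window in cal yr BP: (older bound, younger bound)
HOLOCENE_WINDOW = (11_700.0, 100.0)


@dataclass
class ChronControl:
    """A dated horizon anchoring the age-depth model of one record."""

    depth: float
    age: float
    error: float
    kind: str = "radiocarbon"  # "radiocarbon" | "calendar"

    def __post_init__(self):
        if self.kind not in ("radiocarbon", "calendar"):
            raise ValueError(f"unknown control kind {self.kind!r}")
        if self.error < 0 or (self.kind == "radiocarbon" and self.error <= 0):
            raise ValueError("control error must be positive")


@dataclass
class PollenSample:
    """One depth-indexed pollen count sample.

    ``total_terrestrial`` is ``None`` until harmonization has identified
    which taxa are terrestrial pollen; after harmonization all remaining
    taxa are terrestrial and the total is recorded explicitly.
    """

    depth: float
    counts: Dict[str, int]
    total_terrestrial: Optional[int] = None

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def grain_total(self) -> int:
        """Terrestrial grain total if known, raw total otherwise."""
        return self.total if self.total_terrestrial is None else self.total_terrestrial


@dataclass
class PollenRecord:
    """One site's ordered pollen samples plus chronology and metadata."""

    record_id: str
    lat: float
    lon: float
    samples: List[PollenSample]
    controls: List[ChronControl] = field(default_factory=list)
    continent: Optional[str] = None
    biome: Optional[str] = None
    depositional_environment: Optional[str] = None

    def __post_init__(self):
        if not self.samples:
            raise ValueError(f"record {self.record_id!r} has no samples")
        depths = [s.depth for s in self.samples]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError(
                f"record {self.record_id!r}: sample depths must be strictly increasing"
            )

    @property
    def region(self) -> Optional[str]:
        """Analysis region label (continent by convention)."""
        return self.continent

    @property
    def depths(self) -> np.ndarray:
        return np.array([s.depth for s in self.samples], dtype=float)


class HarmonizationTable:
    """Maps raw taxon names to (harmonized name, group).

    The table is auto-augmented with identity rows for every harmonized
    name so that applying it is idempotent.
    """

    def __init__(self, mapping: Mapping[str, Tuple[str, str]]):
        self._map: Dict[str, Tuple[str, str]] = dict(mapping)
        for raw, (harm, group) in list(self._map.items()):
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r} for taxon {raw!r}")
            self._map.setdefault(harm, (harm, group))

    def __contains__(self, raw: str) -> bool:
        return raw in self._map

    def __getitem__(self, raw: str) -> Tuple[str, str]:
        return self._map[raw]

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"raw": raw, "harmonized": harm, "group": group}
            for raw, (harm, group) in sorted(self._map.items())
        ]
        return pd.DataFrame(rows, columns=["raw", "harmonized", "group"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HarmonizationTable":
        return cls({r.raw: (r.harmonized, r.group) for r in df.itertuples()})

    @classmethod
    def read_csv(cls, path) -> "HarmonizationTable":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


@dataclass
class RegionRect:
    label: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def contains(self, lat: float, lon: float) -> bool:
        # half-open on the max edge so adjacent rectangles stay disjoint
        return (self.lat_min <= lat < self.lat_max) and (
            self.lon_min <= lon < self.lon_max
        )

    def overlaps(self, other: "RegionRect") -> bool:
        return (
            self.lat_min < other.lat_max
            and other.lat_min < self.lat_max
            and self.lon_min < other.lon_max
            and other.lon_min < self.lon_max
        )


class RegionMap:
    """Disjoint axis-aligned rectangles standing in for region polygons."""

    def __init__(self, rects: Sequence[RegionRect]):
        rects = list(rects)
        for i, a in enumerate(rects):
            for b in rects[i + 1 :]:
                if a.overlaps(b):
                    raise InvalidRegionMapError(
                        f"rectangles {a.label!r} and {b.label!r} overlap"
                    )
        self.rects = rects

    @property
    def labels(self) -> List[str]:
        return [r.label for r in self.rects]

    def label_for(self, lat: float, lon: float) -> str:
        hits = [r.label for r in self.rects if r.contains(lat, lon)]
        if not hits:
            raise UnassignedRegionError(
                f"point (lat={lat}, lon={lon}) falls in no region rectangle"
            )
        return hits[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": r.label,
                    "lat_min": r.lat_min,
                    "lat_max": r.lat_max,
                    "lon_min": r.lon_min,
                    "lon_max": r.lon_max,
                }
                for r in self.rects
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionMap":
        return cls(
            [
                RegionRect(str(r.label), r.lat_min, r.lat_max, r.lon_min, r.lon_max)
                for r in df.itertuples()
            ]
        )

    @classmethod
    def read_csv(cls, path) -> "RegionMap":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


@dataclass
class ALCCSeries:
    """Annual regional anthropogenic land-cover fractions, 8,000 -> 100 BP."""

    region: str
    years: np.ndarray  # cal yr BP, descending toward the present
    fraction: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.years.shape != self.fraction.shape:
            raise ValueError("years and fraction must have equal length")
        if np.any(self.fraction < -1e-12) or np.any(self.fraction > 1 + 1e-12):
            raise ValueError("ALCC fractions must lie in [0, 1]")

    def at(self, age) -> np.ndarray:
        """Fraction at ``round(age)``; NaN outside the covered years."""
        age = np.round(np.asarray(age, dtype=float))
        # years are stored descending; index by offset from the first year
        idx = (self.years[0] - age).astype(int)
        out = np.full(age.shape, np.nan)
        ok = (idx >= 0) & (idx < len(self.years))
        out[ok] = self.fraction[idx[ok]]
        return out


# ---------------------------------------------------------------------------
# operations


def apply_harmonization(
    records: Iterable[PollenRecord], table: HarmonizationTable
) -> List[PollenRecord]:
    """Merge synonymous taxa and drop non-terrestrial groups.

    Counts of raw names mapping to one harmonized name are summed; taxa in
    groups other than terrestrial pollen (spores, aquatics, ...) are
    removed and ``total_terrestrial`` recomputed.
    """
    out = []
    for rec in records:
        new_samples = []
        for s in rec.samples:
            merged: Dict[str, int] = {}
            for raw, c in s.counts.items():
                if raw not in table:
                    raise UnmappedTaxonError(raw, rec.record_id)
                harm, group = table[raw]
                if group == TERRESTRIAL:
                    merged[harm] = merged.get(harm, 0) + int(c)
            merged = {k: v for k, v in sorted(merged.items())}
            new_samples.append(
                PollenSample(
                    depth=s.depth,
                    counts=merged,
                    total_terrestrial=int(sum(merged.values())),
                )
            )
        out.append(replace(rec, samples=new_samples))
    return out


def assign_region(record: PollenRecord, region_map: RegionMap) -> PollenRecord:
    """Label a record by the unique rectangle containing its site."""
    label = region_map.label_for(record.lat, record.lon)
    return replace(record, continent=label, biome=label)


def regional_alcc_mean(grid: pd.DataFrame, region_map: RegionMap) -> List[ALCCSeries]:
    """Unweighted per-year mean over grid-cell centres inside each region.

    ``grid`` is long-form with columns ``year, lat, lon, fraction``; the
    lat/lon values are cell centres.
    """
    cells = grid[["lat", "lon"]].drop_duplicates()
    out = []
    for rect in region_map.rects:
        inside = cells[
            (cells.lat >= rect.lat_min)
            & (cells.lat < rect.lat_max)
            & (cells.lon >= rect.lon_min)
            & (cells.lon < rect.lon_max)
        ]
        if inside.empty:
            raise PaleodivError(f"region {rect.label!r} contains no grid cells")
        key = pd.MultiIndex.from_frame(inside)
        sub = grid.set_index(["lat", "lon"]).loc[key].reset_index()
        mean = sub.groupby("year", sort=False)["fraction"].mean()
        mean = mean.sort_index(ascending=False)
        out.append(
            ALCCSeries(
                region=rect.label,
                years=mean.index.to_numpy(dtype=float),
                fraction=mean.to_numpy(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# record I/O


def write_records(records, counts_csv, controls_csv, meta_json) -> None:
    count_rows, ctrl_rows, meta = [], [], {}
    for rec in sorted(records, key=lambda r: r.record_id):
        for s in rec.samples:
            for taxon, c in s.counts.items():
                count_rows.append(
                    {
                        "record_id": rec.record_id,
                        "depth": s.depth,
                        "raw_taxon": taxon,
                        "count": int(c),
                    }
                )
        for c in rec.controls:
            ctrl_rows.append(
                {
                    "record_id": rec.record_id,
                    "depth": c.depth,
                    "age": c.age,
                    "error": c.error,
                    "kind": c.kind,
                }
            )
        meta[rec.record_id] = {
            "lat": rec.lat,
            "lon": rec.lon,
            "continent": rec.continent,
            "biome": rec.biome,
            "depositional_environment": rec.depositional_environment,
        }
    pd.DataFrame(
        count_rows, columns=["record_id", "depth", "raw_taxon", "count"]
    ).to_csv(counts_csv, index=False)
    pd.DataFrame(
        ctrl_rows, columns=["record_id", "depth", "age", "error", "kind"]
    ).to_csv(controls_csv, index=False)
    with open(meta_json, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_records(counts_csv, controls_csv, meta_json) -> List[PollenRecord]:
    counts = pd.read_csv(counts_csv, float_precision="round_trip")
    ctrls = pd.read_csv(controls_csv, float_precision="round_trip")
    with open(meta_json, encoding="utf-8") as fh:
        meta = json.load(fh)

    records = []
    ctrl_by_rec = dict(tuple(ctrls.groupby("record_id"))) if len(ctrls) else {}
    for rid, grp in counts.groupby("record_id", sort=True):
        rid = str(rid)
        samples = []
        for depth, sg in grp.groupby("depth", sort=True):
            samples.append(
                PollenSample(
                    depth=float(depth),
                    counts={
                        str(t): int(c)
                        for t, c in zip(sg.raw_taxon, sg["count"])
                    },
                )
            )
        controls = []
        cg = ctrl_by_rec.get(rid)
        if cg is not None:
            for r in cg.sort_values("depth").itertuples():
                controls.append(
                    ChronControl(
                        depth=float(r.depth),
                        age=float(r.age),
                        error=float(r.error),
                        kind=str(r.kind),
                    )
                )
        m = meta[rid]
        records.append(
            PollenRecord(
                record_id=rid,
                lat=float(m["lat"]),
                lon=float(m["lon"]),
                samples=samples,
                controls=controls,
                continent=m.get("continent"),
                biome=m.get("biome"),
                depositional_environment=m.get("depositional_environment"),
            )
        )
    return records


def write_alcc_grid(grid: pd.DataFrame, path) -> None:
    grid.to_csv(path, index=False)


def read_alcc_grid(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_alcc_series(series: Sequence[ALCCSeries], path) -> None:
    frames = [
        pd.DataFrame({"region": s.region, "year": s.years, "fraction": s.fraction})
        for s in sorted(series, key=lambda s: s.region)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_alcc_series(path) -> Dict[str, ALCCSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for region, grp in df.groupby("region", sort=True):
        grp = grp.sort_values("year", ascending=False)
        out[str(region)] = ALCCSeries(
            region=str(region),
            years=grp.year.to_numpy(dtype=float),
            fraction=grp.fraction.to_numpy(dtype=float),
        )
    return out
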