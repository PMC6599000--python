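"""Synthetic spatially structured multi-isotope data.

Generates the statistical structure the downstream pipeline assumes:
subpopulation polygons tiling a study region, per-isotope "true" surfaces
(smooth geographic trend plus a spatially correlated Gaussian random
field), and georeferenced adult/cub tissue records sampled from those
surfaces with per-isotope measurement noise and age-class offsets
(cubs enriched in 15N and depleted in 13C and 2H relative to adults,
with no 18O contrast — the nursing signature the cohort tests screen for).

Every draw is controlled by the scenario seed; identical scenarios give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point, box, mapping
from shapely.ops import voronoi_diagram

from ._geo import pairwise_haversine_km
from .calibration import ISOTOPES, REFERENCE_MATERIALS, CalibrationLine
from .raster import Grid, Raster

#: Per-isotope analytical measurement error (1 SD, per mil).
MEASUREMENT_SD = {"d13C": 0.1, "d15N": 0.1, "d2H": 2.0, "d18O": 0.4}

#: Default cub-minus-adult offsets (per mil): nursing raises d15N and
#: lowers d13C and d2H; d18O shows no age contrast. Plausible magnitudes,
#: configurable — not literature estimates.
CUB_OFFSETS = {"d13C": -1.3, "d15N": 0.9, "d2H": -20.0, "d18O": 0.0}

_OFFSET_SIGN = {"d13C": -1, "d15N": +1, "d2H": -1, "d18O": 0}

#: Cholesky-based random fields are only practical on modest grids.
MAX_FIELD_CELLS = 3000


@dataclass
class Scenario:
    """Parameters of one synthetic study region.

    Trend coefficients are (intercept, d/dlon, d/dlat) in per mil and per
    mil per degree. ``field_sill`` (per mil^2) and ``field_range_km`` set
    the spatially correlated component C(h) = sill * exp(-h / range) on
    great-circle distance h. With ``plateaus`` set for an isotope, the
    mean surface is a step function over longitudinal bands instead of a
    linear trend.
    """

    bbox: tuple[float, float, float, float] = (-100.0, 58.0, -62.0, 76.0)
    n_subpops: int = 5
    subpop_mode: str = "voronoi"  # or "bands" (equal-width longitudinal strips)
    trends: Mapping[str, tuple[float, float, float]] = dc_field(default_factory=dict)
    plateaus: Mapping[str, Sequence[float]] = dc_field(default_factory=dict)
    plateau_edges: Sequence[float] = ()
    field_sill: Mapping[str, float] = dc_field(default_factory=dict)
    field_range_km: float = 500.0
    noise_sd: Mapping[str, float] = dc_field(default_factory=lambda: dict(MEASUREMENT_SD))
    cub_offsets: Mapping[str, float] = dc_field(default_factory=lambda: dict(CUB_OFFSETS))
    n_adults: int = 100
    n_cubs: int = 16
    year_range: tuple[int, int] = (2005, 2008)
    seed: int = 0

    def __post_init__(self):
        lon_min, lat_min, lon_max, lat_max = self.bbox
        if not (lon_max > lon_min and lat_max > lat_min):
            raise ValueError("degenerate bounding box")
        if self.n_subpops < 2:
            raise ValueError("need at least two subpopulations")
        if self.subpop_mode not in ("voronoi", "bands"):
            raise ValueError("subpop_mode must be 'voronoi' or 'bands'")
        for iso, s in self.field_sill.items():
            if s < 0:
                raise ValueError(f"field_sill[{iso}] must be >= 0")
        if self.field_range_km <= 0:
            raise ValueError("field_range_km must be > 0")
        for iso, s in self.noise_sd.items():
            if s < 0:
                raise ValueError(f"noise_sd[{iso}] must be >= 0")
        for iso, off in self.cub_offsets.items():
            sign = _OFFSET_SIGN.get(iso, 0)
            if sign > 0 and off < 0 or sign < 0 and off > 0 or sign == 0 and off != 0:
                raise ValueError(f"cub offset sign for {iso} contradicts the nursing contrast")

    @property
    def isotopes(self):
        return tuple(iso for iso in ISOTOPES if iso in self.trends or iso in self.plateaus)


def default_scenario(seed: int = 0, **overrides) -> Scenario:
    """Study-region defaults: d13C and d2H higher in the east, d15N higher
    in the west, d18O weakly structured; moderate spatially correlated
    variance on top of the trends."""
    params = dict(
        trends={
            # intercepts chosen so surfaces take realistic hair values near
            # the region centre (lon -81, lat 67)
            "d13C": (-16.0 + 0.08 * 81 - 0.02 * 67, 0.08, 0.02),
            "d15N": (20.5 - 0.05 * 81, -0.05, 0.0),
            "d2H": (-105.0 + 0.9 * 81 + 0.8 * 67, 0.9, -0.8),
            "d18O": (11.0 + 0.01 * 81 + 0.05 * 67, 0.01, -0.05),
        },
        field_sill={"d13C": 0.25, "d15N": 0.2, "d2H": 30.0, "d18O": 0.15},
        field_range_km=500.0,
        seed=seed,
    )
    params.update(overrides)
    return Scenario(**params)


def three_plateau_scenario(separation: float = 3.0, seed: int = 0, **overrides) -> Scenario:
    """Three longitudinal plateau regions with between-region mean steps of
    ``separation`` x the within-region SD in d13C, d15N and d2H (d18O flat),
    sampled as three band subpopulations. The canonical end-to-end recovery
    scenario: three isotopically distinct regions a perfect pipeline should
    rediscover as three spatial clusters."""
    noise = {"d13C": 0.5, "d15N": 0.5, "d2H": 8.0, "d18O": 0.4}
    lon_min, _, lon_max, _ = (-100.0, 58.0, -62.0, 76.0)
    edges = (lon_min + (lon_max - lon_min) / 3.0, lon_min + 2.0 * (lon_max - lon_min) / 3.0)
    step = {iso: separation * noise[iso] for iso in noise}
    params = dict(
        n_subpops=3,
        subpop_mode="bands",
        plateaus={
            # distinct spatial pattern per isotope (monotone east rise for
            # d13C, central low for d15N, eastern high for d2H) so region
            # signatures are non-collinear in isotope space
            "d13C": [-18.0, -18.0 + step["d13C"], -18.0 + 2 * step["d13C"]],
            "d15N": [22.0, 22.0 - step["d15N"], 22.0],
            "d2H": [-130.0, -130.0, -130.0 + step["d2H"]],
            "d18O": [11.0, 11.0, 11.0],
        },
        plateau_edges=edges,
        field_sill={},
        noise_sd=noise,
        n_adults=60,
        n_cubs=10,
        seed=seed,
    )
    params.update(overrides)
    return Scenario(**params)


# ---------------------------------------------------------------------------
# polygons

def generate_subpops(scenario: Scenario) -> list[tuple[str, shapely.Polygon]]:
    """Labelled polygons tiling the scenario bbox.

    Voronoi cells of seeded random centres (default), or equal-width
    longitudinal bands. Polygons are pairwise interior-disjoint and cover
    the bbox exactly.
    """
    lon_min, lat_min, lon_max, lat_max = scenario.bbox
    domain = box(lon_min, lat_min, lon_max, lat_max)
    if scenario.subpop_mode == "bands":
        width = (lon_max - lon_min) / scenario.n_subpops
        return [
            (f"S{i + 1:02d}", box(lon_min + i * width, lat_min, lon_min + (i + 1) * width, lat_max))
            for i in range(scenario.n_subpops)
        ]
    rng = np.random.default_rng([scenario.seed, 11])
    centers = np.column_stack([
        rng.uniform(lon_min, lon_max, scenario.n_subpops),
        rng.uniform(lat_min, lat_max, scenario.n_subpops),
    ])
    cells = voronoi_diagram(MultiPoint(centers.tolist()), envelope=domain)
    out = []
    for i, (cx, cy) in enumerate(centers):
        pt = Point(cx, cy)
        cell = next(g for g in cells.geoms if g.covers(pt))
        out.append((f"S{i + 1:02d}", cell.intersection(domain)))
    return out


def write_polygons_geojson(polygons, path):
    features = [
        {"type": "Feature", "properties": {"label": label}, "geometry": mapping(poly)}
        for label, poly in polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_polygons_geojson(path) -> list[tuple[str, shapely.Polygon]]:
    with open(path) as fh:
        fc = json.load(fh)
    return [
        (f["properties"]["label"], shapely.geometry.shape(f["geometry"]))
        for f in fc["features"]
    ]


# ---------------------------------------------------------------------------
# fields

def _mean_surface(scenario: Scenario, isotope: str, lon, lat):
    if isotope in scenario.plateaus:
        levels = np.asarray(scenario.plateaus[isotope], dtype=float)
        idx = np.searchsorted(np.asarray(scenario.plateau_edges, dtype=float), lon, side="right")
        return levels[idx]
    b0, blon, blat = scenario.trends[isotope]
    return b0 + blon * np.asarray(lon) + blat * np.asarray(lat)


def generate_field(scenario: Scenario, isotope: str, grid: Grid) -> Raster:
    """True surface on ``grid``: mean structure plus (if sill > 0) a
    Gaussian random field with exponential covariance, drawn by Cholesky
    factorisation of the cell-centre covariance."""
    if isotope not in scenario.isotopes:
        raise ValueError(f"scenario defines no surface for {isotope}")
    lon, lat = grid.meshgrid()
    surface = _mean_surface(scenario, isotope, lon, lat).astype(float)
    sill = float(scenario.field_sill.get(isotope, 0.0))
    if sill > 0:
        if grid.size > MAX_FIELD_CELLS:
            raise ValueError(
                f"grid has {grid.size} cells; Cholesky field generation is "
                f"capped at {MAX_FIELD_CELLS}"
            )
        d = pairwise_haversine_km(lon.ravel(), lat.ravel())
        cov = sill * np.exp(-d / scenario.field_range_km)
        cov[np.diag_indices_from(cov)] += 1e-9 * sill
        chol = np.linalg.cholesky(cov)
        rng = np.random.default_rng([scenario.seed, 23, ISOTOPES.index(isotope)])
        surface += (chol @ rng.standard_normal(grid.size)).reshape(grid.nrows, grid.ncols)
    return Raster(grid, surface)


def generate_fields(scenario: Scenario, grid: Grid) -> dict[str, Raster]:
    return {iso: generate_field(scenario, iso, grid) for iso in scenario.isotopes}


# ---------------------------------------------------------------------------
# records

def _uniform_in_polygon(poly, n, rng):
    """Rejection-sample n points uniformly inside a polygon."""
    lon_min, lat_min, lon_max, lat_max = poly.bounds
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = max(4 * (n - len(pts)), 16)
        cand = np.column_stack([
            rng.uniform(lon_min, lon_max, m),
            rng.uniform(lat_min, lat_max, m),
        ])
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        pts = np.vstack([pts, cand[keep]])
    return pts[:n]


def generate_bears(scenario: Scenario, polygons, fields: Mapping[str, Raster]) -> pd.DataFrame:
    """Sample adult and cub records from the true surfaces.

    Locations are uniform within each subpopulation polygon; an adult's
    value is the (bilinearly interpolated) field value at its location plus
    measurement noise, and a cub additionally carries the configured
    age-class offset. Returns the record table sorted deterministically.
    """
    rng = np.random.default_rng([scenario.seed, 57])
    isotopes = [iso for iso in ISOTOPES if iso in fields]
    rows = []
    for label, poly in polygons:
        for age, count in (("adult", scenario.n_adults), ("cub", scenario.n_cubs)):
            if count == 0:
                continue
            pts = _uniform_in_polygon(poly, count, rng)
            years = rng.integers(scenario.year_range[0], scenario.year_range[1] + 1, count)
            vals = {}
            for iso in isotopes:
                base = fields[iso].interp(pts[:, 0], pts[:, 1])
                noise = rng.normal(0.0, scenario.noise_sd.get(iso, 0.0), count)
                off = scenario.cub_offsets.get(iso, 0.0) if age == "cub" else 0.0
                vals[iso] = base + noise + off
            tag = "A" if age == "adult" else "C"
            for i in range(count):
                rows.append({
                    "id": f"{label}-{tag}{i + 1:04d}",
                    "age_class": age,
                    "subpopulation": label,
                    "lon": pts[i, 0],
                    "lat": pts[i, 1],
                    "year": int(years[i]),
                    **{iso: vals[iso][i] for iso in isotopes},
                })
    cols = ["id", "age_class", "subpopulation", "lon", "lat", "year", *ISOTOPES]
    df = pd.DataFrame(rows, columns=cols)
    return df


def write_records_csv(records: pd.DataFrame, path):
    records.to_csv(path, index=False, float_format="%.6f")


def read_records_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# raw instrument readings (inverse of the two-point normalization)

def generate_raw_readings(records: pd.DataFrame,
                          true_calibrations: Mapping[str, CalibrationLine]) -> pd.DataFrame:
    """De-calibrate records into a raw instrument table and append the
    reference-material anchor rows, so that refitting the two-point lines
    and applying them recovers the input exactly."""
    out = records.copy()
    out["role"] = "sample"
    for iso, line in true_calibrations.items():
        if iso in out.columns:
            out[iso] = line.invert(out[iso].to_numpy(dtype=float))
    ref_rows = {}
    for iso, line in true_calibrations.items():
        for name in line.anchors:
            accepted = REFERENCE_MATERIALS.get(name, {}).get(iso)
            if accepted is None:
                continue  # line carries no named anchor for this isotope
            row = ref_rows.setdefault(name, {"id": name, "role": "reference"})
            row[iso] = line.invert(accepted)
    if not ref_rows:
        return out
    return pd.concat([out, pd.DataFrame(ref_rows.values())], ignore_index=True)
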