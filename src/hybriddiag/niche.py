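"""Checklist co-occurrence accounting and niche-overlap geometry.

Implements the occurrence-data side of the hybrid study: counting
checklists in which two species co-occur, the two locality-retention
criteria used to screen out vagrants, 10-km grid thinning, absence-set
construction from consistently surveyed localities, binarization of a
suitability surface at the maximum sensitivity-plus-specificity (Youden)
threshold, and the area/centroid of the overlap between two binarized
surfaces.  The suitability model itself is pluggable; a simple Gaussian
climate-envelope scorer is bundled to exercise thresholding and overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .simulate import ChecklistTable

__all__ = [
    "DEFAULT_EXTENT",
    "EARTH_RADIUS_KM",
    "SuitabilitySurface",
    "OverlapResult",
    "CooccurrenceResult",
    "LocalityFilterResult",
    "find_cooccurrences",
    "filter_localities",
    "thin_grid",
    "build_absence_set",
    "youden_threshold",
    "fit_gaussian_envelope",
    "binarize_and_overlap",
]

DEFAULT_EXTENT = (-105.0, -93.0, 20.0, 35.0)  # lon_min, lon_max, lat_min, lat_max
EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# Suitability surfaces
# ---------------------------------------------------------------------------


@dataclass
class SuitabilitySurface:
    """A regular lon/lat grid of suitability values in [0, 1].

    ``values`` has shape (n_lat, n_lon), row 0 at the southern edge;
    ``lon_edges`` / ``lat_edges`` are the cell boundaries.
    """

    values: np.ndarray
    lon_edges: np.ndarray
    lat_edges: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lon_edges = np.asarray(self.lon_edges, dtype=float)
        self.lat_edges = np.asarray(self.lat_edges, dtype=float)
        if self.values.shape != (len(self.lat_edges) - 1, len(self.lon_edges) - 1):
            raise ValueError("values shape must match grid edges")
        if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1:
            raise ValueError("suitability values must lie in [0, 1]")

    @classmethod
    def empty(
        cls, extent: tuple[float, float, float, float] = DEFAULT_EXTENT, cell_deg: float = 0.25
    ) -> "SuitabilitySurface":
        lon_min, lon_max, lat_min, lat_max = extent
        lon_edges = np.arange(lon_min, lon_max + cell_deg / 2, cell_deg)
        lat_edges = np.arange(lat_min, lat_max + cell_deg / 2, cell_deg)
        values = np.zeros((len(lat_edges) - 1, len(lon_edges) - 1))
        return cls(values, lon_edges, lat_edges)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (
            float(self.lon_edges[0]),
            float(self.lon_edges[-1]),
            float(self.lat_edges[0]),
            float(self.lat_edges[-1]),
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        lon_c = 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])
        lat_c = 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])
        return lon_c, lat_c

    def cell_areas_km2(self) -> np.ndarray:
        """Per-cell spherical-rectangle areas, shape (n_lat, n_lon)."""
        dlon = np.diff(np.radians(self.lon_edges))
        sin_lat = np.sin(np.radians(self.lat_edges))
        band = EARTH_RADIUS_KM**2 * np.diff(sin_lat)  # per latitude band
        return np.outer(band, dlon)

    def sample(self, lons: Sequence[float], lats: Sequence[float]) -> np.ndarray:
        """Suitability values at point locations (cell lookup)."""
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        i = np.clip(np.searchsorted(self.lat_edges, lats, "right") - 1, 0, self.values.shape[0] - 1)
        j = np.clip(np.searchsorted(self.lon_edges, lons, "right") - 1, 0, self.values.shape[1] - 1)
        return self.values[i, j]


@dataclass
class OverlapResult:
    """Binarized surfaces, their intersection, and its geometry."""

    binary_a: np.ndarray
    binary_b: np.ndarray
    overlap: np.ndarray
    area_km2: float
    centroid: tuple[float, float] | None
    polygons: object = None  # shapely geometry of the overlap cells

    def to_geojson(self) -> dict:
        features = []
        if self.polygons is not None and not self.polygons.is_empty:
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(self.polygons),
                    "properties": {"area_km2": self.area_km2},
                }
            )
        return {"type": "FeatureCollection", "features": features}


# ---------------------------------------------------------------------------
# Checklist accounting
# ---------------------------------------------------------------------------


@dataclass
class CooccurrenceResult:
    n_checklists: int
    n_localities: int
    per_year: pd.Series


def _detected(table: ChecklistTable, species: str) -> pd.Series:
    return table.records["species"].apply(lambda sp: species in sp)


def find_cooccurrences(
    table: ChecklistTable, species_a: str, species_b: str
) -> CooccurrenceResult:
    """Count complete checklists recording both species in the same survey."""
    rec = table.records
    both = _detected(table, species_a) & _detected(table, species_b) & rec["complete"]
    co = rec[both]
    per_year = co["date"].dt.year.value_counts().sort_index()
    return CooccurrenceResult(
        n_checklists=int(len(co)),
        n_localities=int(co["locality_id"].nunique()),
        per_year=per_year,
    )


@dataclass
class LocalityFilterResult:
    retained: pd.DataFrame  # observations of the species at retained localities
    removed: pd.DataFrame  # per removed locality: which criteria failed
    retained_localities: list = field(default_factory=list)


def filter_localities(
    table: ChecklistTable,
    species: str,
    window: tuple[str, str] = ("2019-01-01", "2023-05-31"),
    min_years: int = 2,
    min_rate: float = 0.5,
) -> LocalityFilterResult:
    """Screen out vagrant-driven localities with two retention criteria.

    A locality's observations of ``species`` are retained iff (1) the
    species was reported there in at least ``min_years`` distinct years
    within ``window``, OR (2) it was detected on at least ``min_rate`` of
    all checklists ever submitted at that locality (all-time denominator).
    """
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if hi < lo:
        raise ValueError("invalid window")
    rec = table.records
    det = _detected(table, species)
    obs = rec[det]

    all_time_checklists = rec.groupby("locality_id").size()
    all_time_detections = obs.groupby("locality_id").size()

    in_window = obs[(obs["date"] >= lo) & (obs["date"] <= hi)]
    years_detected = in_window.groupby("locality_id")["date"].apply(
        lambda d: d.dt.year.nunique()
    )

    removed_rows = []
    retained_locs = []
    for loc in obs["locality_id"].unique():
        c1 = int(years_detected.get(loc, 0)) >= min_years
        rate = all_time_detections.get(loc, 0) / all_time_checklists[loc]
        c2 = rate >= min_rate
        if c1 or c2:
            retained_locs.append(loc)
        else:
            removed_rows.append((loc, not c1, not c2))
    retained = obs[obs["locality_id"].isin(retained_locs)].reset_index(drop=True)
    removed = pd.DataFrame(
        removed_rows, columns=["locality_id", "failed_min_years", "failed_min_rate"]
    )
    return LocalityFilterResult(
        retained=retained, removed=removed, retained_localities=retained_locs
    )


def thin_grid(
    points: pd.DataFrame | np.ndarray,
    cell_km: float = 10.0,
    seed: int | np.random.Generator | None = None,
    center_lat: float | None = None,
) -> pd.DataFrame:
    """Retain a single point per ``cell_km`` grid cell, chosen uniformly.

    Cells are built in an equal-distance approximation: longitudes are
    scaled by cos(latitude of the extent center) before binning, so cells
    are ~square in kilometres.  Idempotent and seed-reproducible.
    """
    if isinstance(points, np.ndarray):
        points = pd.DataFrame(points, columns=["lon", "lat"])
    if len(points) == 0:
        return points.copy()
    rng = np.random.default_rng(seed)
    lat0 = center_lat if center_lat is not None else float(points["lat"].mean())
    km_per_deg = 2 * np.pi * EARTH_RADIUS_KM / 360.0
    x = points["lon"].to_numpy() * km_per_deg * np.cos(np.radians(lat0))
    y = points["lat"].to_numpy() * km_per_deg
    cells = list(zip(np.floor(x / cell_km).astype(int), np.floor(y / cell_km).astype(int)))
    keep_idx = []
    by_cell: dict = {}
    for idx, cell in zip(points.index, cells):
        by_cell.setdefault(cell, []).append(idx)
    for cell in sorted(by_cell):
        members = by_cell[cell]
        keep_idx.append(members[int(rng.integers(0, len(members)))])
    return points.loc[sorted(keep_idx)].copy()


def build_absence_set(
    table: ChecklistTable,
    species: str,
    years: Iterable[int] = range(2019, 2024),
) -> pd.DataFrame:
    """Localities with at least one checklist in EVERY listed year and zero
    detections of the species over those years."""
    years = sorted(set(int(y) for y in years))
    if not years:
        raise ValueError("empty year set")
    rec = table.records
    in_years = rec[rec["date"].dt.year.isin(years)]
    surveyed_years = in_years.groupby("locality_id")["date"].apply(
        lambda d: set(d.dt.year)
    )
    fully_surveyed = [loc for loc, ys in surveyed_years.items() if set(years) <= ys]
    det = in_years[_detected(table, species).reindex(in_years.index, fill_value=False)]
    detected_locs = set(det["locality_id"])
    absent = [loc for loc in fully_surveyed if loc not in detected_locs]
    locs = table.localities()
    return locs[locs["locality_id"].isin(absent)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Thresholding and overlap
# ---------------------------------------------------------------------------


def youden_threshold(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Threshold maximizing sensitivity + specificity (Youden's J).

    Candidate cutpoints are the midpoints between consecutive distinct
    observed scores; a point is predicted present when its score exceeds
    the threshold.  Ties are broken toward the lowest such threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both presence and absence classes must be represented")
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("all scores are equal; no separating threshold exists")
    candidates = 0.5 * (uniq[:-1] + uniq[1:])
    best_thr, best_j = None, -np.inf
    for thr in candidates:
        pred = scores > thr
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        j = sens + spec
        if j > best_j + 1e-12:
            best_j, best_thr = j, float(thr)
    return best_thr


def fit_gaussian_envelope(
    presence_lonlat: pd.DataFrame | np.ndarray,
    surface: SuitabilitySurface | None = None,
    shrinkage: float = 1e-3,
) -> SuitabilitySurface:
    """Bundled default suitability scorer: a Gaussian envelope over presence
    coordinates.  Scores each grid cell by the Mahalanobis distance of its
    center to the presence cloud, mapped through exp(-d^2/2) into [0, 1].
    Exercises thresholding/overlap; it is not an ecological model of record.
    """
    if isinstance(presence_lonlat, pd.DataFrame):
        pts = presence_lonlat[["lon", "lat"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(presence_lonlat, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least three presence points")
    if surface is None:
        surface = SuitabilitySurface.empty()
    mu = pts.mean(axis=0)
    cov = np.cov(pts.T) + shrinkage * np.eye(2)
    prec = np.linalg.inv(cov)
    lon_c, lat_c = surface.cell_centers()
    gx, gy = np.meshgrid(lon_c, lat_c)
    d = np.stack([gx - mu[0], gy - mu[1]], axis=-1)
    m2 = np.einsum("...i,ij,...j->...", d, prec, d)
    values = np.exp(-0.5 * m2)
    return SuitabilitySurface(values, surface.lon_edges, surface.lat_edges)


def binarize_and_overlap(
    surface_a: SuitabilitySurface,
    surface_b: SuitabilitySurface,
    thr_a: float,
    thr_b: float,
) -> OverlapResult:
    """Binarize two suitability surfaces at their thresholds and intersect.

    Cells strictly above the threshold become 1; the overlap is the
    per-cell AND.  Area is the sum of spherical-rectangle cell areas (km²,
    latitude-corrected); the centroid is the area-weighted mean of the
    overlapping cell centers; polygons are the union of overlap cell boxes.
    """
    if (
        surface_a.values.shape != surface_b.values.shape
        or not np.allclose(surface_a.lon_edges, surface_b.lon_edges)
        or not np.allclose(surface_a.lat_edges, surface_b.lat_edges)
    ):
        raise ValueError("surfaces must share an identical grid")
    bin_a = surface_a.values > thr_a
    bin_b = surface_b.values > thr_b
    overlap = bin_a & bin_b
    areas = surface_a.cell_areas_km2()
    area = float(areas[overlap].sum())
    if overlap.any():
        lon_c, lat_c = surface_a.cell_centers()
        gx, gy = np.meshgrid(lon_c, lat_c)
        w = areas[overlap]
        centroid = (
            float(np.average(gx[overlap], weights=w)),
            float(np.average(gy[overlap], weights=w)),
        )
        boxes = [
            box(
                surface_a.lon_edges[j],
                surface_a.lat_edges[i],
                surface_a.lon_edges[j + 1],
                surface_a.lat_edges[i + 1],
            )
            for i, j in zip(*np.nonzero(overlap))
        ]
        polygons = unary_union(boxes)
    else:
        centroid = None
        polygons = unary_union([])
    return OverlapResult(
        binary_a=bin_a,
        binary_b=bin_b,
        overlap=overlap,
        area_km2=area,
        centroid=centroid,
        polygons=polygons,
    )
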