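"""Raster grids, occurrence records, data preparation, and partial-ROC evaluation.

Rasters are plain ESRI ASCII grids (the text interchange dialect used by most
niche-modeling toolchains); occurrences are CSV tables with columns
``species,lon,lat`` in WGS84 degrees.  Data preparation mirrors standard
niche-modeling practice: spatial thinning of occurrences (minimum great-circle
separation plus one record per grid cell) and greedy pruning of collinear
environmental layers at a Pearson-r threshold.  Suitability surfaces are
evaluated with the partial-ROC AUC-ratio bootstrap restricted to a maximum
acceptable omission error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridLayer", "OccurrenceSet", "PartialROCResult", "GridFormatError",
    "read_grid", "write_grid", "read_occurrences", "write_occurrences",
    "thin_occurrences", "prune_correlated_layers", "extract_values",
    "pearson_valid", "partial_roc",
]

EARTH_RADIUS_KM = 6371.0


class GridFormatError(ValueError):
    """Raised for malformed ESRI ASCII grid files."""


@dataclass
class GridLayer:
    """Rectangular georeferenced raster, row-major from the NW corner."""

    nrows: int
    ncols: int
    west: float        # x of the lower-left corner, degrees
    south: float       # y of the lower-left corner, degrees
    cellsize: float    # degrees
    nodata: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nrows, self.ncols):
            raise ValueError(
                f"values shape {self.values.shape} != ({self.nrows}, {self.ncols})")

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.cellsize

    @property
    def north(self) -> float:
        return self.south + self.nrows * self.cellsize

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values) & (self.values != self.nodata)

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask()]

    def aligned_with(self, other: "GridLayer") -> bool:
        return (self.nrows == other.nrows and self.ncols == other.ncols
                and np.isclose(self.west, other.west)
                and np.isclose(self.south, other.south)
                and np.isclose(self.cellsize, other.cellsize))

    def cell_of(self, lon, lat):
        """(row, col) of the cell containing each point; row 0 is the N edge."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.west) / self.cellsize).astype(int)
        row = self.nrows - 1 - np.floor((lat - self.south) / self.cellsize).astype(int)
        return row, col

    def cell_center(self, row, col):
        lon = self.west + (np.asarray(col) + 0.5) * self.cellsize
        lat = self.south + (self.nrows - np.asarray(row) - 0.5) * self.cellsize
        return lon, lat


@dataclass
class OccurrenceSet:
    species: str
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self) -> None:
        self.lon = np.atleast_1d(np.asarray(self.lon, dtype=float))
        self.lat = np.atleast_1d(np.asarray(self.lat, dtype=float))
        if self.lon.shape != self.lat.shape:
            raise ValueError("lon/lat length mismatch")

    def __len__(self) -> int:
        return len(self.lon)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"species": self.species, "lon": self.lon, "lat": self.lat})


@dataclass
class PartialROCResult:
    auc_ratios: np.ndarray
    mean_ratio: float
    p_value: float          # one-sided Z-test for mean ratio > 1
    p_boot: float           # bootstrap proportion of ratios <= 1
    E: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_grid(path) -> GridLayer:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridFormatError(f"{path}: missing header fields {missing}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    for j, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        vals = np.fromstring(line, sep=" ")
        if len(vals) != ncols:
            raise GridFormatError(f"{path}: line {j}: expected {ncols} values, got {len(vals)}")
        rows.append(vals)
    if len(rows) != nrows:
        raise GridFormatError(f"{path}: expected {nrows} data rows, got {len(rows)}")
    return GridLayer(nrows=nrows, ncols=ncols, west=header["xllcorner"],
                     south=header["yllcorner"], cellsize=header["cellsize"],
                     nodata=header["nodata_value"], values=np.vstack(rows))


def write_grid(layer: GridLayer, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {layer.ncols}\n")
        fh.write(f"nrows {layer.nrows}\n")
        fh.write(f"xllcorner {layer.west:.10g}\n")
        fh.write(f"yllcorner {layer.south:.10g}\n")
        fh.write(f"cellsize {layer.cellsize:.10g}\n")
        fh.write(f"NODATA_value {layer.nodata:.10g}\n")
        for row in layer.values:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_occurrences(path) -> dict[str, OccurrenceSet]:
    """Read a species,lon,lat CSV into per-species occurrence sets."""
    df = pd.read_csv(path)
    need = {"species", "lon", "lat"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: occurrence CSV needs columns {sorted(need)}")
    return {sp: OccurrenceSet(sp, g["lon"].to_numpy(), g["lat"].to_numpy())
            for sp, g in df.groupby("species", sort=True)}


def write_occurrences(occs: dict[str, OccurrenceSet] | list[OccurrenceSet], path) -> None:
    sets = occs.values() if isinstance(occs, dict) else occs
    pd.concat([o.to_frame() for o in sets], ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preparation

def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a 6371-km sphere."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def thin_occurrences(occ: OccurrenceSet, min_dist_km: float,
                     grid: GridLayer | None = None, seed=None,
                     order: str = "distance_first") -> OccurrenceSet:
    """Spatially thin occurrence records.

    Randomly (under ``seed``) removes points so that no two retained points
    lie within ``min_dist_km`` great-circle km, and (when ``grid`` is given)
    at most one point remains per grid cell.  ``order`` selects whether the
    distance pass or the cell-deduplication pass runs first.  Already-thinned
    input passes through unchanged, so the operation is idempotent.
    """
    if min_dist_km < 0:
        raise ValueError("min_dist_km must be >= 0")
    if order not in ("distance_first", "cell_first"):
        raise ValueError("order must be 'distance_first' or 'cell_first'")
    if len(occ) == 0:
        return OccurrenceSet(occ.species, np.empty(0), np.empty(0))
    rng = np.random.default_rng(seed)
    keep = np.arange(len(occ))

    def dist_pass(idx: np.ndarray) -> np.ndarray:
        if min_dist_km == 0:
            # still drop exact duplicates
            seen, kept = set(), []
            for i in idx:
                key = (occ.lon[i], occ.lat[i])
                if key not in seen:
                    seen.add(key)
                    kept.append(i)
            return np.array(kept, dtype=int)
        shuffled = rng.permutation(idx)
        kept: list[int] = []
        for i in shuffled:
            if all(haversine_km(occ.lon[i], occ.lat[i], occ.lon[j], occ.lat[j]) >= min_dist_km
                   for j in kept):
                kept.append(int(i))
        return np.array(sorted(kept), dtype=int)

    def cell_pass(idx: np.ndarray) -> np.ndarray:
        if grid is None:
            return idx
        row, col = grid.cell_of(occ.lon[idx], occ.lat[idx])
        kept: dict[tuple[int, int], int] = {}
        shuffled = rng.permutation(len(idx))
        for k in shuffled:
            key = (int(row[k]), int(col[k]))
            if key not in kept:
                kept[key] = int(idx[k])
        return np.array(sorted(kept.values()), dtype=int)

    passes = (dist_pass, cell_pass) if order == "distance_first" else (cell_pass, dist_pass)
    for p in passes:
        keep = p(keep)
    return OccurrenceSet(occ.species, occ.lon[keep], occ.lat[keep])


def pearson_valid(a: GridLayer, b: GridLayer) -> float:
    """Pearson correlation over cells valid in both layers."""
    if not a.aligned_with(b):
        raise ValueError("layers are not aligned (shape/origin/cellsize differ)")
    m = a.valid_mask() & b.valid_mask()
    x, y = a.values[m], b.values[m]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return 1.0 if np.allclose(x, y) else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def prune_correlated_layers(layers: dict[str, GridLayer], r_max: float = 0.75,
                            priority: list[str] | None = None) -> list[str]:
    """Greedy collinearity pruning: keep a layer iff |r| < r_max against all kept.

    Layers are scanned in ``priority`` order (default: input order), so
    ecologically preferred layers should be listed first.
    """
    if not 0 < r_max < 1:
        raise ValueError("r_max must be in (0, 1)")
    if not layers:
        raise ValueError("need at least one layer")
    names = priority if priority is not None else list(layers)
    unknown = [n for n in names if n not in layers]
    if unknown:
        raise ValueError(f"priority names not among layers: {unknown}")
    kept: list[str] = []
    for name in names:
        if all(abs(pearson_valid(layers[name], layers[k])) < r_max for k in kept):
            kept.append(name)
    return kept


def extract_values(layer: GridLayer, occ: OccurrenceSet) -> np.ndarray:
    """Containing-cell lookup of layer values at occurrence points.

    Points outside the layer extent are excluded with a warning; points on
    nodata cells yield NaN.
    """
    inside = ((occ.lon >= layer.west) & (occ.lon < layer.east)
              & (occ.lat >= layer.south) & (occ.lat < layer.north))
    if not inside.all():
        warnings.warn(f"{int((~inside).sum())} point(s) outside layer extent excluded",
                      stacklevel=2)
    row, col = layer.cell_of(occ.lon[inside], occ.lat[inside])
    vals = layer.values[row, col].astype(float)
    vals[vals == layer.nodata] = np.nan
    return vals


# ---------------------------------------------------------------------------
# Partial ROC

def _roc_curve(cell_classes: np.ndarray, n_classes: int, point_classes: np.ndarray):
    """Proportion-of-area (x) and sensitivity (y) at descending thresholds.

    Class c covers suitability bin c; threshold "class >= c" for c from
    n_classes down to 0 gives a monotone curve from (0, 0) to (1, 1).
    """
    area_counts = np.bincount(cell_classes, minlength=n_classes + 1)
    pt_counts = np.bincount(point_classes, minlength=n_classes + 1)
    # cumulative from the top class downward
    x = np.concatenate([[0.0], np.cumsum(area_counts[::-1]) / len(cell_classes)])
    y = np.concatenate([[0.0], np.cumsum(pt_counts[::-1]) / len(point_classes)])
    return x, y


def _partial_auc_ratio(x: np.ndarray, y: np.ndarray, E: float) -> float:
    """AUC ratio over the region where sensitivity >= 1 - E.

    Model area = integral of y dx over x in [x0, 1] where x0 is the
    (interpolated) area at which sensitivity first reaches 1 - E; null area is
    the same integral of the chance diagonal y = x.
    """
    s = 1.0 - E
    idx = np.searchsorted(y, s, side="left")
    if idx >= len(y):
        return np.nan
    if idx == 0 or y[idx] == y[idx - 1]:
        x0, y0 = x[idx], y[idx]
        xs = np.concatenate([[x0], x[idx:]])
        ys = np.concatenate([[y0], y[idx:]])
    else:
        # linear interpolation of the crossing point
        f = (s - y[idx - 1]) / (y[idx] - y[idx - 1])
        x0 = x[idx - 1] + f * (x[idx] - x[idx - 1])
        xs = np.concatenate([[x0], x[idx:]])
        ys = np.concatenate([[s], y[idx:]])
    model = float(np.trapezoid(ys, xs))
    null = 0.5 * (1.0 - xs[0] ** 2)
    if null <= 0:
        return np.nan
    return model / null


def partial_roc(suitability: GridLayer, test_points: OccurrenceSet,
                E: float = 0.05, boot_frac: float = 0.5, n_boot: int = 1000,
                seed=None, n_classes: int = 100) -> PartialROCResult:
    """Partial-ROC evaluation of a suitability surface against test points.

    Bootstraps ``boot_frac`` of the test points (with replacement) ``n_boot``
    times; each replicate yields the ratio of the model's partial AUC to the
    chance (diagonal) partial AUC over the high-sensitivity region
    (sensitivity >= 1 - E).  Ratios above 1 indicate better-than-random
    prediction; significance is a one-sided Z-test on the bootstrap ratios.
    """
    if not 0 < E < 0.5:
        raise ValueError("omission error E must be in (0, 0.5)")
    vals = suitability.valid_values()
    pts = extract_values(suitability, test_points)
    pts = pts[np.isfinite(pts)]
    if len(pts) < 5:
        raise ValueError("need at least 5 test points with valid suitability")
    lo, hi = float(vals.min()), float(vals.max())
    span = hi - lo
    if span == 0:
        cell_classes = np.zeros(len(vals), dtype=int)
        pt_classes = np.zeros(len(pts), dtype=int)
    else:
        cell_classes = np.clip(((vals - lo) / span * n_classes).astype(int), 0, n_classes)
        pt_classes = np.clip(((pts - lo) / span * n_classes).astype(int), 0, n_classes)

    rng = np.random.default_rng(seed)
    m = max(int(round(boot_frac * len(pts))), 1)
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        sample = rng.choice(pt_classes, size=m, replace=True)
        x, y = _roc_curve(cell_classes, n_classes, sample)
        ratios[b] = _partial_auc_ratio(x, y, E)
    valid = ratios[np.isfinite(ratios)]
    degenerate = len(valid) < n_boot // 2
    if len(valid) == 0:
        return PartialROCResult(ratios, np.nan, np.nan, np.nan, E, degenerate=True)
    mean = float(np.mean(valid))
    sd = float(np.std(valid, ddof=1))
    if sd == 0:
        p = 0.5 if mean == 1.0 else (0.0 if mean > 1 else 1.0)
    else:
        from scipy.stats import norm
        p = float(norm.sf((mean - 1.0) / sd))
    p_boot = float(np.mean(valid <= 1.0))
    return PartialROCResult(ratios, mean, p, p_boot, E, degenerate=degenerate)
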