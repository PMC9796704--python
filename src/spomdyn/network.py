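"""Patch networks, detection histories and the file formats that carry them.

A metapopulation analysis starts from two tables: the patch network
(``patch_id, x_km, y_km, length_km``, optionally an explicit inter-patch
distance matrix) and a long-format detection history
(``patch_id, year, visit, detected``).  Both live here as lightweight
array-backed containers together with CSV readers/writers and an ESRI
ASCII grid writer for raster outputs such as colonization surfaces.

Distances are planar Euclidean in km unless an explicit matrix is
supplied (the escape hatch for, e.g., along-waterway distances).  Patch
"size" is the riparian patch length A_i in km, not an area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PatchNetwork",
    "DetectionHistory",
    "OccupancyState",
    "read_patch_table",
    "write_patch_table",
    "read_detection_history",
    "write_detection_history",
    "write_raster_ascii",
    "read_raster_ascii",
]


def pairwise_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between patch reference points (km)."""
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    return np.hypot(dx, dy)


@dataclass
class PatchNetwork:
    """A set of habitat patches with coordinates, lengths and distances.

    Parameters
    ----------
    patch_id
        Unique patch identifiers, order defines the patch index used
        everywhere downstream.
    x, y
        Planar coordinates in km.
    length
        Patch length A_i in km; strictly positive.
    dist
        Optional explicit symmetric distance matrix (km).  When omitted
        it is computed from the coordinates.
    """

    patch_id: list
    x: np.ndarray
    y: np.ndarray
    length: np.ndarray
    dist: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        self.patch_id = list(self.patch_id)
        n = len(self.patch_id)
        if n < 1:
            raise ValueError("network needs at least one patch")
        if len(set(map(str, self.patch_id))) != n:
            raise ValueError("duplicate patch ids")
        for arr, name in ((self.x, "x"), (self.y, "y"), (self.length, "length")):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        if np.any(self.length <= 0):
            raise ValueError("patch lengths must be strictly positive")
        if self.dist is None:
            self.dist = pairwise_distances(self.x, self.y)
            off = self.dist[~np.eye(n, dtype=bool)]
            if n > 1 and np.any(off <= 0):
                raise ValueError(
                    "coincident patch coordinates; supply an explicit "
                    "distance matrix if this is intended"
                )
        else:
            self.dist = np.asarray(self.dist, dtype=float)
            if self.dist.shape != (n, n):
                raise ValueError(f"distance matrix must be {n}x{n}")
            if not np.allclose(self.dist, self.dist.T):
                raise ValueError("distance matrix must be symmetric")
            if np.any(np.diag(self.dist) != 0):
                raise ValueError("distance matrix must have a zero diagonal")
            if n > 1 and np.any(self.dist[~np.eye(n, dtype=bool)] <= 0):
                raise ValueError("off-diagonal distances must be positive")

    @property
    def n(self) -> int:
        return len(self.patch_id)

    def index_of(self, pid) -> int:
        try:
            return self.patch_id.index(pid)
        except ValueError:
            raise KeyError(f"unknown patch id: {pid!r}") from None

    def bounding_box(self, buffer: float = 0.0):
        """(xmin, ymin, xmax, ymax) of the patch points, optionally buffered."""
        return (
            float(self.x.min() - buffer),
            float(self.y.min() - buffer),
            float(self.x.max() + buffer),
            float(self.y.max() + buffer),
        )


@dataclass
class DetectionHistory:
    """Detection/non-detection data y[i, t, j] with missing visits as NaN.

    ``visits`` (J_{i,t}) counts the non-missing visits of each patch-year;
    a patch-year may be entirely unsurveyed (J = 0).
    """

    y: np.ndarray  # (n, T, V_max) float, values {0.0, 1.0, nan}
    years: np.ndarray  # (T,) int year labels, ascending

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.years = np.asarray(self.years)
        if self.y.ndim != 3:
            raise ValueError("y must be patch x year x visit")
        if self.y.shape[1] != len(self.years):
            raise ValueError("year axis mismatch")
        vals = self.y[~np.isnan(self.y)]
        if not np.all((vals == 0) | (vals == 1)):
            raise ValueError("detections must be 0, 1 or missing")
        if len(self.years) > 1 and np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly ascending")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def T(self) -> int:
        return self.y.shape[1]

    @property
    def v_max(self) -> int:
        return self.y.shape[2]

    @property
    def visits(self) -> np.ndarray:
        """J_{i,t}: number of surveyed visits per patch-year."""
        return (~np.isnan(self.y)).sum(axis=2)

    @property
    def detections(self) -> np.ndarray:
        """Count of detections per patch-year (missing visits contribute 0)."""
        return np.nansum(self.y, axis=2).astype(int)

    def naive_occupancy(self) -> np.ndarray:
        """(n, T) 0/1: any detection in the patch-year counts as occupied.

        Unsurveyed patch-years are 0 — naive occupancy ignores imperfect
        detection by construction.
        """
        return (self.detections > 0).astype(np.int8)


@dataclass
class OccupancyState:
    """Latent (or true) patch-by-year occupancy matrix z[i, t] in {0,1}."""

    z: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z)
        if self.z.ndim != 2:
            raise ValueError("z must be patch x year")
        if not np.all((self.z == 0) | (self.z == 1)):
            raise ValueError("occupancy states must be 0 or 1")
        self.z = self.z.astype(np.int8)

    @property
    def n(self) -> int:
        return self.z.shape[0]

    @property
    def T(self) -> int:
        return self.z.shape[1]

    def mean_occupancy(self) -> float:
        return float(self.z.mean())


# ---------------------------------------------------------------------------
# tabular I/O

_PATCH_COLS = ["patch_id", "x_km", "y_km", "length_km"]


def read_patch_table(path, distance_path=None) -> PatchNetwork:
    """Read a patch network from ``patches.csv`` (+ optional distance matrix).

    The distance CSV, when given, is a square matrix with patch ids as the
    first column and as header; row/column order must match the patch table.
    """
    df = pd.read_csv(path)
    missing = [c for c in _PATCH_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"patch table missing columns: {missing}")
    dist = None
    if distance_path is not None:
        dmat = pd.read_csv(distance_path, index_col=0)
        ids = [str(p) for p in df["patch_id"]]
        if list(map(str, dmat.index)) != ids or list(map(str, dmat.columns)) != ids:
            raise ValueError("distance matrix ids do not match patch table order")
        dist = dmat.to_numpy(dtype=float)
    return PatchNetwork(
        patch_id=list(df["patch_id"]),
        x=df["x_km"].to_numpy(),
        y=df["y_km"].to_numpy(),
        length=df["length_km"].to_numpy(),
        dist=dist,
    )


def write_patch_table(network: PatchNetwork, path) -> None:
    pd.DataFrame(
        {
            "patch_id": network.patch_id,
            "x_km": network.x,
            "y_km": network.y,
            "length_km": network.length,
        }
    ).to_csv(path, index=False)


def read_detection_history(path, network: PatchNetwork) -> DetectionHistory:
    """Read a long-format detection table against a known patch network.

    Columns: ``patch_id, year, visit, detected`` with detected in {0, 1, NA}.
    Cells with no record are missing; visit labels are 1-based.
    """
    df = pd.read_csv(path)
    needed = ["patch_id", "year", "visit", "detected"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"detection table missing columns: {missing}")
    if df.duplicated(subset=["patch_id", "year", "visit"]).any():
        raise ValueError("duplicate (patch, year, visit) rows")
    vals = df["detected"].dropna()
    if not vals.isin([0, 1]).all():
        raise ValueError("detected must be 0, 1 or NA")
    years = np.sort(df["year"].unique())
    if len(years) > 1 and np.any(np.diff(years) != 1):
        raise ValueError("year sequence has gaps; dynamics assume a unit step")
    v_max = int(df["visit"].max())
    if df["visit"].min() < 1:
        raise ValueError("visit labels are 1-based")
    year_index = {int(yr): t for t, yr in enumerate(years)}
    y = np.full((network.n, len(years), v_max), np.nan)
    for row in df.itertuples(index=False):
        i = network.index_of(row.patch_id)
        t = year_index[int(row.year)]
        j = int(row.visit) - 1
        if not pd.isna(row.detected):
            y[i, t, j] = float(row.detected)
    return DetectionHistory(y=y, years=years)


def write_detection_history(hist: DetectionHistory, network: PatchNetwork, path) -> None:
    """Write the long-format table; missing visits are omitted entirely."""
    rows = []
    for i, pid in enumerate(network.patch_id):
        for t, year in enumerate(hist.years):
            for j in range(hist.v_max):
                v = hist.y[i, t, j]
                if not np.isnan(v):
                    rows.append((pid, int(year), j + 1, int(v)))
    pd.DataFrame(rows, columns=["patch_id", "year", "visit", "detected"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# ESRI ASCII grid

_NODATA = -9999.0


def write_raster_ascii(grid, origin, cellsize, path) -> None:
    """Write a 2-D matrix as an ESRI ASCII grid.

    ``grid`` row 0 is the *top* (north) row, as rasters are conventionally
    stored; ``origin`` is the lower-left corner (xllcorner, yllcorner) in km.
    NaN cells are written as the NODATA value.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or grid.size == 0:
        raise ValueError("grid must be a non-empty 2-D matrix")
    if cellsize <= 0:
        raise ValueError("cellsize must be positive")
    nrows, ncols = grid.shape
    body = np.where(np.isnan(grid), _NODATA, grid)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin[0]:.6f}\n")
        fh.write(f"yllcorner {origin[1]:.6f}\n")
        fh.write(f"cellsize {cellsize:.6f}\n")
        fh.write(f"NODATA_value {_NODATA:g}\n")
        for row in body:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_raster_ascii(path):
    """Read an ESRI ASCII grid; returns (grid, origin, cellsize)."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    grid = np.array([[float(v) for v in line.split()] for line in lines[6:]])
    grid[grid == header["nodata_value"]] = np.nan
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid body does not match header dimensions")
    return grid, (header["xllcorner"], header["yllcorner"]), header["cellsize"]
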