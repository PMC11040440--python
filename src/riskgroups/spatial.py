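"""Sliding-window spatial mortality-risk mapping.

A 250 m x 250 m window slides across the study area in 10 m steps.  Each
grid node aggregates the children whose household falls in the half-open
window [x, x+250) x [y, y+250); nodes covering fewer than 100 children are
masked to avoid small-cell estimates.  Risks are adjusted for the linear
decline of mortality with birth year by fitting one global weighted
linear-probability trend and averaging per-child residuals within each
window: node value = (global risk at the reference year + weighted mean
residual) x 100.

Window sums are computed with an integral image (summed-area table) over
step-sized cells, which is exactly equivalent to the brute-force per-window
loop (tested against it).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimates import EffectEstimate
from .weights import WeightedCohort

NODATA = -9999.0


@dataclass(frozen=True)
class AreaCircle:
    """A circular candidate high-risk area."""

    center: tuple[float, float]
    radius: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        return (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2 <= self.radius**2


@dataclass(frozen=True)
class SurfaceGeometry:
    x0: float
    y0: float
    step: float
    window: float
    nx: int  # nodes along x
    ny: int  # nodes along y

    @property
    def cells_per_window(self) -> int:
        return int(round(self.window / self.step))

    def node_origin(self, i: int, j: int) -> tuple[float, float]:
        """Lower-left corner of window (i, j); i indexes x, j indexes y."""
        return self.x0 + self.step * i, self.y0 + self.step * j

    def node_center(self, i: int, j: int) -> tuple[float, float]:
        ox, oy = self.node_origin(i, j)
        return ox + self.window / 2.0, oy + self.window / 2.0


@dataclass
class RiskSurface:
    """Trend-adjusted risk per window node; masked nodes carry NaN."""

    geometry: SurfaceGeometry
    risk: np.ndarray          # (ny, nx) per-100, NaN where masked
    count: np.ndarray         # (ny, nx) unweighted child count
    weighted_count: np.ndarray
    reference_year: float
    global_risk: float        # per-100 adjusted risk at the reference year
    min_count: int

    def argmax_node(self) -> tuple[int, int]:
        """(i, j) of the unmasked node with the highest risk (non-inferential)."""
        if np.all(np.isnan(self.risk)):
            raise ValueError("surface is fully masked")
        j, i = np.unravel_index(np.nanargmax(self.risk), self.risk.shape)
        return int(i), int(j)


def _grid_geometry(bbox, step: float, window: float) -> tuple[SurfaceGeometry, int, int]:
    x0, y0, x1, y1 = bbox
    ncx = int(np.floor((x1 - x0) / step))
    ncy = int(np.floor((y1 - y0) / step))
    k = int(round(window / step))
    if ncx < k or ncy < k:
        raise ValueError("bounding box smaller than one window")
    return SurfaceGeometry(x0, y0, step, window, ncx - k + 1, ncy - k + 1), ncx, ncy


def _window_sums(cells: np.ndarray, k: int) -> np.ndarray:
    """Sum of every k x k block of `cells` via a summed-area table."""
    sat = np.zeros((cells.shape[0] + 1, cells.shape[1] + 1))
    sat[1:, 1:] = cells.cumsum(axis=0).cumsum(axis=1)
    return sat[k:, k:] - sat[:-k, k:] - sat[k:, :-k] + sat[:-k, :-k]


def scan(
    wc: WeightedCohort,
    bbox: tuple[float, float, float, float],
    min_count: int = 100,
    reference_year: float | None = None,
    step: float = 10.0,
    window: float = 250.0,
) -> RiskSurface:
    """Slide the window over the study area and map trend-adjusted risk."""
    if len(wc.data) == 0:
        raise ValueError("empty cohort")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    geom, ncx, ncy = _grid_geometry(bbox, step, window)
    x = wc.data["x"].to_numpy(dtype=float)
    y = wc.data["y"].to_numpy(dtype=float)
    if (x < bbox[0]).any() or (x > bbox[2]).any() or (y < bbox[1]).any() or (y > bbox[3]).any():
        raise ValueError("coordinates outside the bounding box")
    outcome = wc.data["died"].to_numpy(dtype=float)
    year = wc.data["birth_year"].to_numpy(dtype=float)
    if reference_year is None:
        reference_year = (year.min() + year.max()) / 2.0

    X = sm.add_constant(pd.DataFrame({"year_c": year - reference_year}))
    trend = sm.WLS(outcome, X, weights=wc.weights).fit()
    global_risk = float(trend.params["const"])  # adjusted risk at reference year
    residual = outcome - np.asarray(trend.predict(X))

    ix = np.clip(((x - bbox[0]) / step).astype(int), 0, ncx - 1)
    iy = np.clip(((y - bbox[1]) / step).astype(int), 0, ncy - 1)
    flat = iy * ncx + ix
    size = ncx * ncy
    count = np.bincount(flat, minlength=size).reshape(ncy, ncx).astype(float)
    wsum = np.bincount(flat, weights=wc.weights, minlength=size).reshape(ncy, ncx)
    rsum = np.bincount(flat, weights=wc.weights * residual, minlength=size).reshape(ncy, ncx)

    k = geom.cells_per_window
    wcount = _window_sums(count, k)
    wweight = _window_sums(wsum, k)
    wresid = _window_sums(rsum, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        risk = (global_risk + wresid / wweight) * 100.0
    masked = (wcount < min_count) | (wweight <= 0)
    risk[masked] = np.nan
    return RiskSurface(
        geometry=geom,
        risk=risk,
        count=wcount,
        weighted_count=wweight,
        reference_year=float(reference_year),
        global_risk=global_risk * 100.0,
        min_count=min_count,
    )


def window_membership(x: float, y: float, geom: SurfaceGeometry) -> set[tuple[int, int]]:
    """All grid nodes whose half-open window contains the point (up to 625)."""
    k = geom.cells_per_window
    if x < geom.x0 or y < geom.y0:
        return set()
    cx = int(np.floor((x - geom.x0) / geom.step))
    cy = int(np.floor((y - geom.y0) / geom.step))
    if cx >= geom.nx + k - 1 or cy >= geom.ny + k - 1:
        return set()
    xs = range(max(0, cx - k + 1), min(geom.nx - 1, cx) + 1)
    ys = range(max(0, cy - k + 1), min(geom.ny - 1, cy) + 1)
    return {(i, j) for i in xs for j in ys}


def area_effect(
    wc: WeightedCohort,
    circle: AreaCircle,
    calendar: str = "birth_year",
    method: str = "glm",
) -> EffectEstimate:
    """Calendar-adjusted risk difference for living inside vs outside a circle."""
    from . import effects

    inside = circle.contains(wc.data["x"].to_numpy(), wc.data["y"].to_numpy())
    if inside.all() or not inside.any():
        raise ValueError("circle must leave children on both sides")
    if method == "glm":
        return effects.glm_risk_difference(wc, inside, (calendar,))
    if method == "tmle":
        est, _ = effects.tmle_risk_difference(wc, inside, (calendar,))
        return est
    raise ValueError(f"unknown method {method!r}")


def export_surface(surface: RiskSurface, path: str | Path, format: str | None = None) -> Path:
    """Write the surface as an ESRI ASCII grid (.asc) or float32 TIFF (.tif).

    Masked nodes become NODATA (.asc) or NaN (.tif).  Values round-trip
    losslessly at float32 precision via read_surface.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    grid = surface.risk.astype(np.float32)
    if format == "asc":
        out = np.where(np.isnan(grid), np.float32(NODATA), grid)
        header = (
            f"ncols {surface.geometry.nx}\n"
            f"nrows {surface.geometry.ny}\n"
            f"xllcorner {surface.geometry.x0}\n"
            f"yllcorner {surface.geometry.y0}\n"
            f"cellsize {surface.geometry.step}\n"
            f"NODATA_value {NODATA}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            # ASCII grids run north to south: top row = largest y
            np.savetxt(fh, out[::-1], fmt="%.9g")
        return path
    if format in ("tif", "tiff"):
        import tifffile

        tifffile.imwrite(path, grid[::-1])
        return path
    raise ValueError(f"unknown format {format!r}")


def read_surface(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a surface written by export_surface; returns (risk grid, header)."""
    path = Path(path)
    if path.suffix.lower() == ".asc":
        header: dict = {}
        with open(path) as fh:
            for _ in range(6):
                key, value = fh.readline().split()
                header[key.lower()] = float(value)
            grid = np.loadtxt(fh, dtype=np.float32)
        grid = np.atleast_2d(grid)[::-1].copy()
        grid[grid == np.float32(header["nodata_value"])] = np.nan
        return grid, header
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        grid = tifffile.imread(path)[::-1].copy()
        return grid, {}
    raise ValueError(f"unknown surface format {path.suffix!r}")
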