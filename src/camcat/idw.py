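"""Inverse distance weighting of per-site detection frequencies onto a grid.

Each site contributes its detection frequency — the proportion of survey
replicates in which the species was detected, ``y_total / n`` — and every
grid cell takes the distance-decay weighted average

    v(c) = Σ_k d_k^(-power) v_k / Σ_k d_k^(-power),

so interpolated values are convex combinations of the inputs (bounded by the
input extremes) and a cell coinciding with a site reproduces the site's value
exactly. Planar (projected) coordinates are assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import DetectionHistory

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: lower-left corner, square cell size, rows × cols."""

    x_min: float
    y_min: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")

    @classmethod
    def from_points(cls, x, y, cell_size: float, margin: float = 0.0) -> "GridSpec":
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        x0, y0 = x.min() - margin, y.min() - margin
        n_cols = max(1, int(np.ceil((x.max() + margin - x0) / cell_size)))
        n_rows = max(1, int(np.ceil((y.max() + margin - y0) / cell_size)))
        return cls(x_min=x0, y_min=y0, cell_size=cell_size,
                   n_rows=n_rows, n_cols=n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates; row 0 is the northernmost row."""
        xs = self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_min + (np.arange(self.n_rows)[::-1] + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class RasterGrid:
    """Interpolated surface; ``values`` row 0 is the top (north) row."""

    spec: GridSpec
    values: np.ndarray
    nodata: float = NODATA

    def to_long_frame(self) -> pd.DataFrame:
        cx, cy = self.spec.cell_centers()
        return pd.DataFrame({
            "x": cx.ravel(), "y": cy.ravel(), "value": self.values.ravel(),
        })


def site_detection_frequency(
    history: DetectionHistory, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Per-site detection frequency y_total / n with planar coordinates."""
    if (history.n < 1).any():
        raise ValueError("every site needs at least one surveyed occasion")
    cov = covariates.set_index("site_id").loc[history.sites]
    return pd.DataFrame({
        "site_id": history.sites,
        "x": cov["x"].to_numpy(float),
        "y": cov["y"].to_numpy(float),
        "value": history.y_total / history.n,
    })


def idw_interpolate(
    points: pd.DataFrame,
    grid_spec: GridSpec,
    power: float = 2.0,
    max_points: int | None = None,
    eps: float = 1e-9,
) -> RasterGrid:
    """Inverse-distance-weighted surface from point values.

    ``points`` needs columns x, y, value. With ``max_points`` set, only the
    nearest k sites contribute to each cell; otherwise all do.
    """
    if len(points) == 0:
        raise ValueError("no points to interpolate")
    px = points["x"].to_numpy(float)
    py = points["y"].to_numpy(float)
    pv = points["value"].to_numpy(float)
    stacked = np.column_stack([px, py])
    _, first = np.unique(stacked, axis=0, return_index=True)
    if len(first) < len(points):
        dup = np.setdiff1d(np.arange(len(points)), first)
        for i in dup:
            same = (px == px[i]) & (py == py[i])
            if np.ptp(pv[same]) > 0:
                raise ValueError("duplicate coordinates with conflicting values")

    cx, cy = grid_spec.cell_centers()
    d = np.hypot(cx.ravel()[:, None] - px[None, :],
                 cy.ravel()[:, None] - py[None, :])  # (cells, points)
    if max_points is not None and max_points < len(points):
        kth = np.partition(d, max_points - 1, axis=1)[:, max_points - 1]
        mask = d > kth[:, None]
    else:
        mask = np.zeros_like(d, dtype=bool)

    values = np.empty(d.shape[0])
    exact = d < eps
    has_exact = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        w = np.where(mask, 0.0, d ** (-power))
    w[has_exact] = 0.0
    np.putmask(values, ~has_exact, (w @ pv)[~has_exact] / w.sum(axis=1)[~has_exact])
    for i in np.flatnonzero(has_exact):
        values[i] = pv[np.argmax(exact[i])]
    return RasterGrid(spec=grid_spec,
                      values=values.reshape(grid_spec.n_rows, grid_spec.n_cols))


def write_asc(raster: RasterGrid, path) -> None:
    """Write the surface as an ESRI ASCII grid (plain text)."""
    s = raster.spec
    with open(path, "w") as fh:
        fh.write(f"ncols {s.n_cols}\n")
        fh.write(f"nrows {s.n_rows}\n")
        fh.write(f"xllcorner {s.x_min:.6f}\n")
        fh.write(f"yllcorner {s.y_min:.6f}\n")
        fh.write(f"cellsize {s.cell_size:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata:.1f}\n")
        for row in raster.values:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
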