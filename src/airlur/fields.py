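"""Scalar fields on regular grids: bilinear sampling and Gaussian random fields.

The synthetic city stores elevation and population as plain numpy grids in
projected meter coordinates; spatially correlated noise in the ground-truth
pollution surfaces is a Gaussian random field with exponential covariance,
simulated exactly on a coarse grid (Cholesky) and interpolated bilinearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CoverageError(ValueError):
    """A receptor falls outside the extent of a raster layer."""


@dataclass(frozen=True)
class RasterField:
    """A scalar field on a regular grid of square cells.

    ``values[i, j]`` is the cell whose lower-left corner is
    ``(x0 + j*cell, y0 + i*cell)``; rows run south to north. Sampling is
    bilinear between cell centers, clamped to the outermost centers, and
    raises :class:`CoverageError` outside the raster extent.
    """

    x0: float
    y0: float
    cell: float
    values: np.ndarray  # (nrows, ncols)

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell,
            self.y0 + self.nrows * self.cell,
        )

    def sample(self, x, y):
        """Bilinear sample at (x, y); arrays broadcast elementwise."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.bounds
        eps = 1e-9 * max(self.cell, 1.0)
        if np.any(x < xmin - eps) or np.any(x > xmax + eps) or np.any(
            y < ymin - eps
        ) or np.any(y > ymax + eps):
            raise CoverageError("sample point outside raster extent")
        # grid coordinates relative to cell centers
        gx = np.clip((x - self.x0) / self.cell - 0.5, 0.0, self.ncols - 1.0)
        gy = np.clip((y - self.y0) / self.cell - 0.5, 0.0, self.nrows - 1.0)
        j0 = np.clip(np.floor(gx).astype(int), 0, self.ncols - 2) if self.ncols > 1 else np.zeros_like(gx, dtype=int)
        i0 = np.clip(np.floor(gy).astype(int), 0, self.nrows - 2) if self.nrows > 1 else np.zeros_like(gy, dtype=int)
        j1 = np.minimum(j0 + 1, self.ncols - 1)
        i1 = np.minimum(i0 + 1, self.nrows - 1)
        fx = gx - j0
        fy = gy - i0
        v = self.values
        out = (
            v[i0, j0] * (1 - fx) * (1 - fy)
            + v[i0, j1] * fx * (1 - fy)
            + v[i1, j0] * (1 - fx) * fy
            + v[i1, j1] * fx * fy
        )
        return out if out.shape else float(out)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.nrows) + 0.5) * self.cell
        return xs, ys


# Cholesky factors are expensive and depend only on grid geometry and the
# correlation range, not on the seed, so they are cached process-wide.
_CHOL_CACHE: dict[tuple, np.ndarray] = {}


def _grf_nodes(bounds, nx, ny):
    x0, y0, x1, y1 = bounds
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(y0, y1, ny)
    gx, gy = np.meshgrid(xs, ys)
    return xs, ys, np.column_stack([gx.ravel(), gy.ravel()])


def _chol_factor(bounds, nx, ny, corr_range) -> np.ndarray:
    key = (tuple(round(b, 6) for b in bounds), nx, ny, round(corr_range, 6))
    fac = _CHOL_CACHE.get(key)
    if fac is None:
        _, _, pts = _grf_nodes(bounds, nx, ny)
        d = np.sqrt(
            (pts[:, None, 0] - pts[None, :, 0]) ** 2
            + (pts[:, None, 1] - pts[None, :, 1]) ** 2
        )
        cov = np.exp(-d / corr_range)
        cov[np.diag_indices_from(cov)] += 1e-8
        fac = np.linalg.cholesky(cov)
        _CHOL_CACHE[key] = fac
    return fac


@dataclass(frozen=True)
class GaussianRandomField:
    """One realization of a stationary Gaussian field with exponential covariance.

    Marginal SD ``sd``, correlation range ``corr_range`` (the e-folding
    distance of the covariance), realized on an ``nx`` x ``ny`` node grid over
    ``bounds`` and interpolated bilinearly in between.
    """

    bounds: tuple[float, float, float, float]
    sd: float
    corr_range: float
    nx: int = 25
    ny: int = 35
    _raster: RasterField = field(init=False, repr=False, default=None)

    @classmethod
    def realize(cls, bounds, sd, corr_range, rng: np.random.Generator, nx=25, ny=35):
        fld = cls(tuple(bounds), float(sd), float(corr_range), nx, ny)
        if sd == 0:
            z = np.zeros(nx * ny)
        else:
            L = _chol_factor(fld.bounds, nx, ny, corr_range)
            z = sd * (L @ rng.standard_normal(nx * ny))
        x0, y0, x1, y1 = fld.bounds
        # node grid rendered as a raster whose cell centers coincide with nodes
        dx = (x1 - x0) / (nx - 1)
        dy = (y1 - y0) / (ny - 1)
        cell = dx  # square-ish; sampling only ever uses x/y separately
        raster = RasterField(
            x0 - 0.5 * dx, y0 - 0.5 * dy, dx, z.reshape(ny, nx)
        )
        object.__setattr__(fld, "_raster", _AnisoRaster(x0, y0, dx, dy, z.reshape(ny, nx)))
        return fld

    def sample(self, x, y):
        return self._raster.sample(x, y)


class _AnisoRaster:
    """Internal bilinear interpolator on a node grid with distinct x/y spacing."""

    def __init__(self, x0, y0, dx, dy, values):
        self.x0, self.y0, self.dx, self.dy = x0, y0, dx, dy
        self.values = values

    def sample(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ny, nx = self.values.shape
        gx = np.clip((x - self.x0) / self.dx, 0.0, nx - 1.0)
        gy = np.clip((y - self.y0) / self.dy, 0.0, ny - 1.0)
        j0 = np.clip(np.floor(gx).astype(int), 0, nx - 2)
        i0 = np.clip(np.floor(gy).astype(int), 0, ny - 2)
        fx = gx - j0
        fy = gy - i0
        v = self.values
        out = (
            v[i0, j0] * (1 - fx) * (1 - fy)
            + v[i0, j0 + 1] * fx * (1 - fy)
            + v[i0 + 1, j0] * (1 - fx) * fy
            + v[i0 + 1, j0 + 1] * fx * fy
        )
        return out if out.shape else float(out)
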