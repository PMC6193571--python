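"""Spatial grid, autocorrelated environmental fields, and dispersal.

Environments live on a rectangular cell grid (default 50 x 50).  Each of
the L environmental variables (default 5) is an independent draw of a
Gaussian random field whose covariance between two cells at Euclidean
distance d is exp(-phi * d), realized by a Cholesky factorization of the
full cell-by-cell covariance matrix.  Draws are standardized to sample
mean 0 and variance 1 over cells, so a variable is directly usable as a
dimensionless regressor.

Individuals of the first generations are placed uniformly at random;
later generations disperse from their mother's cell with a lognormally
distributed distance and uniform direction, reflected at grid boundaries.
Limited dispersal over an autocorrelated field is what makes relatives
share environments -- the structural confound the model suite exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from pedvar.pedigree import UNKNOWN


@dataclass(frozen=True)
class GridSpec:
    width: int = 50
    height: int = 50

    def __post_init__(self):
        if self.width < 2 or self.height < 2:
            raise ValueError("grid must be at least 2 x 2")

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    def cell_coords(self) -> np.ndarray:
        """(n_cells, 2) array of (x, y) cell coordinates, row-major in y."""
        xs, ys = np.meshgrid(np.arange(self.width), np.arange(self.height))
        return np.column_stack([xs.ravel(), ys.ravel()])

    def cell_index(self, x, y) -> np.ndarray:
        return np.asarray(y) * self.width + np.asarray(x)


@dataclass
class EnvField:
    """Realized environmental variables, one value per cell per variable."""

    grid: GridSpec
    values: np.ndarray  # (n_cells, L)
    phi: float

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def at(self, x, y) -> np.ndarray:
        """Environmental vector(s) at cell (x, y)."""
        return self.values[self.grid.cell_index(x, y)]

    def to_frame(self) -> pd.DataFrame:
        coords = self.grid.cell_coords()
        cols = {f"k{l + 1}": self.values[:, l] for l in range(self.n_vars)}
        return pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], **cols})


def field_cholesky(grid: GridSpec, phi: float) -> np.ndarray:
    """Lower Cholesky factor of the exp(-phi * d) cell covariance matrix.

    Expensive (n_cells^3); compute once and pass to
    :func:`simulate_env_field` when drawing many replicate fields.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    coords = grid.cell_coords().astype(float)
    C = np.exp(-phi * squareform(pdist(coords)))
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        C[np.diag_indices_from(C)] += 1e-10
        return np.linalg.cholesky(C)


def simulate_env_field(
    grid: GridSpec = GridSpec(),
    phi: float = 0.15,
    n_vars: int = 5,
    seed: int | np.random.Generator = 0,
    chol: np.ndarray | None = None,
) -> EnvField:
    """Draw ``n_vars`` independent autocorrelated fields on the grid.

    Each field is standardized to exact sample mean 0 / variance 1 over
    cells, and the fields are decorrelated over cells so their sample
    covariances are negligible by construction.  Both steps are linear
    maps across same-kernel fields, so each variable remains a Gaussian
    field with between-cell correlation exp(-phi * d).
    """
    rng = np.random.default_rng(seed)
    L = field_cholesky(grid, phi) if chol is None else chol
    z = L @ rng.standard_normal((grid.n_cells, n_vars))
    z -= z.mean(axis=0)
    if n_vars > 1:
        # whiten the sample cross-covariance: a linear combination of
        # independent fields with the same kernel keeps that kernel
        cov = (z.T @ z) / len(z)
        z = z @ np.linalg.inv(np.linalg.cholesky(cov)).T
    z -= z.mean(axis=0)
    z /= z.std(axis=0)
    return EnvField(grid=grid, values=z, phi=phi)


def _reflect(v: np.ndarray, n: int) -> np.ndarray:
    """Fold integer coordinates into [0, n-1] by reflection at both edges."""
    if n == 1:
        return np.zeros_like(v)
    period = 2 * (n - 1)
    v = np.mod(v, period)
    return np.where(v > n - 1, period - v, v)


def place_individuals(
    ped: pd.DataFrame,
    grid: GridSpec = GridSpec(),
    dispersal_mu: float = 1.0,
    dispersal_sigma2: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Locations for every pedigree member (columns ``id, x, y``).

    Phantom founders (generation 0) and the first real generation are
    placed uniformly at random.  Each later individual starts at its dam's
    cell and moves a distance drawn from lognormal(mu, sigma^2) (cell
    units) in a uniform direction, rounded to the nearest cell and
    reflected at the boundaries.
    """
    rng = np.random.default_rng(seed)
    ids = ped["id"].to_numpy()
    gen = ped["generation"].to_numpy()
    dam = ped["dam"].to_numpy()

    x = np.zeros(len(ids), dtype=int)
    y = np.zeros(len(ids), dtype=int)
    loc_of = {}

    for g in np.unique(gen):
        mask = gen == g
        n = int(mask.sum())
        if g <= 1:
            gx = rng.integers(0, grid.width, size=n)
            gy = rng.integers(0, grid.height, size=n)
        else:
            dams = dam[mask]
            if np.any(dams == UNKNOWN):
                raise ValueError("non-founder without a located dam")
            dx0 = np.array([loc_of[int(d)][0] for d in dams], dtype=float)
            dy0 = np.array([loc_of[int(d)][1] for d in dams], dtype=float)
            dist = rng.lognormal(dispersal_mu, np.sqrt(dispersal_sigma2), size=n)
            theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
            gx = _reflect(np.rint(dx0 + dist * np.cos(theta)).astype(int), grid.width)
            gy = _reflect(np.rint(dy0 + dist * np.sin(theta)).astype(int), grid.height)
        x[mask] = gx
        y[mask] = gy
        for i, xi, yi in zip(ids[mask], gx, gy):
            loc_of[int(i)] = (int(xi), int(yi))

    return pd.DataFrame({"id": ids, "x": x, "y": y})


def assign_environments(loc: pd.DataFrame, field: EnvField) -> pd.DataFrame:
    """Per-individual environmental vectors: verbatim field values at each cell.

    Returns a DataFrame ``id, k1..kL``.
    """
    x = loc["x"].to_numpy()
    y = loc["y"].to_numpy()
    if np.any((x < 0) | (x >= field.grid.width) | (y < 0) | (y >= field.grid.height)):
        raise ValueError("locations outside the grid")
    vals = field.at(x, y)
    out = pd.DataFrame({"id": loc["id"].to_numpy()})
    for l in range(field.n_vars):
        out[f"k{l + 1}"] = vals[:, l]
    return out
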