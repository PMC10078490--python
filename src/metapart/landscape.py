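"""Spatial scaffolding: site configurations, Moran eigenvector maps, distances.

Moran eigenvector maps (MEMs) provide an orthogonal, centered spatial basis
derived from a site connectivity matrix. Broad-scale (positively autocorrelated)
patterns correspond to eigenvectors with large positive eigenvalues; fine-scale
(negatively autocorrelated) patterns to negative eigenvalues. The basis is used
three ways here: to simulate spatially autocorrelated environments and
communities, to measure spatial autocorrelation (Moran's I), and to build
spectrally randomized surrogates for the environmental-fraction correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "Landscape",
    "build_mem_basis",
    "simulate_landscape",
    "haversine_km",
    "distance_matrix",
    "max_pairwise_distance_km",
    "morans_i",
]


@dataclass
class Landscape:
    """A set of sites with coordinates and their Moran eigenvector basis.

    Attributes
    ----------
    site_id : list of str
        Site labels, one per row of ``coords``.
    coords : ndarray of shape (n_sites, 2)
        Columns are (x, y) in arbitrary planar units, or (lon, lat) in decimal
        degrees when ``geographic`` is True.
    geographic : bool
        Whether coordinates are decimal degrees (distances are then great-circle).
    mem_basis : ndarray of shape (n_sites, n_sites - 1)
        Moran eigenvector map values; columns are centered, mutually orthogonal
        unit vectors ordered by decreasing eigenvalue (broad scale first).
    mem_eigenvalues : ndarray of shape (n_sites - 1,)
        Eigenvalues of the doubly centered connectivity matrix, decreasing.
    connectivity : ndarray
        The binary spatial weight matrix the basis was derived from.
    """

    site_id: list[str]
    coords: np.ndarray
    geographic: bool
    mem_basis: np.ndarray
    mem_eigenvalues: np.ndarray
    connectivity: np.ndarray = field(repr=False, default=None)

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    @property
    def n_positive_mem(self) -> int:
        """Number of broad-scale (positive-eigenvalue) eigenvectors."""
        return int(np.sum(self.mem_eigenvalues > 1e-10))


def haversine_km(coords_a: np.ndarray, coords_b: np.ndarray | None = None) -> np.ndarray:
    """Great-circle distance matrix (km) between (lon, lat) points in degrees."""
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = a if coords_b is None else np.atleast_2d(np.asarray(coords_b, dtype=float))
    lon_a, lat_a = np.radians(a[:, 0])[:, None], np.radians(a[:, 1])[:, None]
    lon_b, lat_b = np.radians(b[:, 0])[None, :], np.radians(b[:, 1])[None, :]
    dlat = lat_b - lat_a
    dlon = lon_b - lon_a
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat_a) * np.cos(lat_b) * np.sin(dlon / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def distance_matrix(coords: np.ndarray, geographic: bool = False) -> np.ndarray:
    """Pairwise site distances: Euclidean (planar) or haversine (geographic)."""
    coords = np.asarray(coords, dtype=float)
    if geographic:
        _validate_degrees(coords)
        return haversine_km(coords)
    return squareform(pdist(coords))


def _validate_degrees(coords: np.ndarray) -> None:
    lon, lat = coords[:, 0], coords[:, 1]
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("coordinate out of range: lat must be in [-90, 90], lon in [-180, 180]")


def max_pairwise_distance_km(coords: np.ndarray) -> float:
    """Maximum great-circle distance (km) over all site pairs.

    Coordinates are (lon, lat) decimal degrees, WGS84 sphere of radius 6371 km.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    _validate_degrees(coords)
    return float(haversine_km(coords).max())


def build_mem_basis(
    coords: np.ndarray, geographic: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distance-based Moran eigenvector maps for a site configuration.

    Connectivity is binary: sites closer than (or equal to) the longest edge of
    the minimum spanning tree of the distance matrix are neighbors. The weight
    matrix is doubly centered and eigendecomposed; all n-1 nontrivial
    eigenvectors are kept (the trivial constant direction is removed by
    centering), ordered by decreasing eigenvalue so that broad-scale, positively
    autocorrelated patterns come first.

    Returns
    -------
    basis : (n, n-1) ndarray — centered orthonormal columns
    eigenvalues : (n-1,) ndarray — decreasing
    weights : (n, n) ndarray — the binary connectivity matrix
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 4:
        raise ValueError("insufficient sites for spatial basis")
    dmat = distance_matrix(coords, geographic=geographic)
    mst = minimum_spanning_tree(dmat).toarray()
    threshold = mst.max()
    weights = ((dmat <= threshold + 1e-12) & (dmat > 0)).astype(float)
    weights = np.maximum(weights, weights.T)  # symmetry

    # Eigendecompose W restricted to the centered subspace: columns of the
    # Helmert sub-basis span {z : sum(z)=0} orthonormally, so the resulting
    # eigenvectors are exactly centered and mutually orthogonal even when the
    # spectrum is degenerate.
    helmert = _helmert_basis(n)
    restricted = helmert.T @ weights @ helmert
    restricted = (restricted + restricted.T) / 2.0
    eigval, eigvec = np.linalg.eigh(restricted)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    basis = helmert @ eigvec[:, order]
    flip = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(basis.shape[1])])
    flip[flip == 0] = 1.0
    basis = basis * flip
    return basis, eigval, weights


def _helmert_basis(n: int) -> np.ndarray:
    """Orthonormal (n, n-1) basis of the zero-sum subspace."""
    h = np.zeros((n, n - 1))
    for j in range(1, n):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.sqrt(j * (j + 1))
    return h


def simulate_landscape(
    n_sites: int,
    extent: float = 1.0,
    seed: int = 0,
    geographic: bool = False,
) -> Landscape:
    """Scatter sites uniformly over a square and build their MEM basis.

    With ``geographic=True`` the square is interpreted in decimal degrees
    (anchored near the equator so the extent is roughly isotropic in km) and
    distances are great-circle.
    """
    if n_sites < 4:
        raise ValueError("insufficient sites for spatial basis")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, extent, size=(n_sites, 2))
    basis, eigval, weights = build_mem_basis(coords, geographic=geographic)
    return Landscape(
        site_id=[f"site_{i:03d}" for i in range(n_sites)],
        coords=coords,
        geographic=geographic,
        mem_basis=basis,
        mem_eigenvalues=eigval,
        connectivity=weights,
    )


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I of ``values`` under the spatial weight matrix ``weights``.

    I = (n / S0) * (z' W z) / (z' z) with z the centered values and S0 the sum
    of all weights. Expectation under no autocorrelation is -1/(n-1).
    """
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    n = z.size
    s0 = weights.sum()
    denom = float(z @ z)
    if denom == 0.0 or s0 == 0.0:
        raise ValueError("zero variance or empty weight matrix")
    return float(n / s0 * (z @ weights @ z) / denom)
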