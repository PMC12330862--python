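"""Spatial-autocorrelation diagnostics and nonparametric inference.

Variogram (Matheron), Moran's I, an FWHM proxy derived from the variogram,
the modal power spectrum, the Pearson test statistic, and surrogate-based
two-tailed p-values with Westfall-Young max-statistic FWE correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import PairDistances, SurfaceMap, TriangleMesh

__all__ = [
    "Variogram", "NullTest", "pearson_r", "variogram", "morans_i",
    "build_weights", "estimate_fwhm", "modal_power_spectrum",
    "nonparametric_p", "fwe_correct", "null_test",
]


def _as_map(m) -> SurfaceMap:
    return m if isinstance(m, SurfaceMap) else SurfaceMap(np.asarray(m, dtype=np.float64))


def pearson_r(y, z) -> float:
    """Sample correlation over the joint valid mask of two maps."""
    y, z = _as_map(y), _as_map(z)
    if y.n_vertices != z.n_vertices:
        raise ValueError("maps have different lengths")
    joint = y.mask & z.mask
    if joint.sum() < 3:
        raise ValueError("fewer than 3 jointly valid vertices")
    a, b = y.values[joint], z.values[joint]
    if np.ptp(a) == 0:
        raise ValueError("first map has zero variance on the joint mask")
    if np.ptp(b) == 0:
        raise ValueError("second map has zero variance on the joint mask")
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


@dataclass
class Variogram:
    """Matheron semivariance per distance bin; empty bins hold nan."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray

    def nonempty(self):
        ok = self.counts > 0
        return self.bin_centers[ok], self.gamma[ok]


def variogram(surface_map, distances: PairDistances, bins: int = 25,
              max_lag: float | None = None) -> Variogram:
    """gamma(h) = (1 / 2|N(h)|) * sum over pairs in the bin of (y_i - y_j)^2.

    Pairs touching a masked vertex are excluded.  Default max_lag is a
    quarter of the largest sampled pair distance.
    """
    m = _as_map(surface_map)
    pairs, d = distances.pairs, distances.distances
    ok = m.mask[pairs[:, 0]] & m.mask[pairs[:, 1]]
    pairs, d = pairs[ok], d[ok]
    if max_lag is None:
        max_lag = 0.25 * distances.distances.max()
    edges = np.linspace(0.0, max_lag, bins + 1)
    inside = (d > 0) & (d <= max_lag)
    idx = np.clip(np.searchsorted(edges, d[inside], side="left") - 1, 0, bins - 1)
    diff2 = (m.values[pairs[inside, 0]] - m.values[pairs[inside, 1]]) ** 2
    counts = np.bincount(idx, minlength=bins)
    sums = np.bincount(idx, weights=diff2, minlength=bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * counts), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Variogram(edges, centers, gamma, counts)


def build_weights(source, scheme: str = "inverse-distance",
                  n_vertices: int | None = None) -> sp.csr_matrix:
    """Spatial weight matrix for Moran's I.

    'inverse-distance' takes a PairDistances set and weights each sampled
    pair by 1/d; 'adjacency' takes a TriangleMesh and weights mesh edges 1.
    Symmetric with zero diagonal.  ``n_vertices`` fixes the matrix size when
    the pair set is a subsample of a larger mesh.
    """
    if scheme == "inverse-distance":
        if not isinstance(source, PairDistances):
            raise TypeError("inverse-distance weights require a PairDistances")
        p, d = source.pairs, source.distances
        pos = d > 0
        p, d = p[pos], d[pos]
        n = n_vertices if n_vertices is not None else int(p.max()) + 1
        w = sp.coo_matrix((1.0 / d, (p[:, 0], p[:, 1])), shape=(n, n))
        return (w + w.T).tocsr()
    if scheme == "adjacency":
        if not isinstance(source, TriangleMesh):
            raise TypeError("adjacency weights require a TriangleMesh")
        e = source.edges
        n = source.n_vertices
        w = sp.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
        return (w + w.T).tocsr()
    raise ValueError(f"unknown scheme {scheme!r}")


def morans_i(surface_map, weights: sp.spmatrix) -> float:
    """Global Moran's I over the valid vertices.

    I = (n / sum w) * sum_ij w_ij (y_i - ybar)(y_j - ybar) / sum_i (y_i - ybar)^2
    """
    m = _as_map(surface_map)
    w = sp.csr_matrix(weights)
    if w.shape[0] != w.shape[1]:
        raise ValueError("weights must be square")
    if w.shape[0] != m.n_vertices:
        # weights built on a vertex subsample: restrict the map accordingly
        raise ValueError("weights size does not match map length")
    if np.any(w.diagonal() != 0):
        raise ValueError("weights must have zero diagonal")
    if w.data.size and w.data.min() < 0:
        raise ValueError("weights must be nonnegative")
    mask = m.mask
    w = w[mask][:, mask]
    if w.sum() <= 0:
        raise ValueError("no positive weights among valid vertices")
    y = m.values[mask]
    dev = y - y.mean()
    denom = dev @ dev
    if denom == 0:
        raise ValueError("map has zero variance")
    return float(len(y) / w.sum() * (dev @ (w @ dev)) / denom)


def estimate_fwhm(surface_map, distances: PairDistances, bins: int = 25,
                  max_lag: float | None = None) -> float:
    """FWHM of the effective spatial autocorrelation kernel.

    Uses the variogram proxy rho(h) = 1 - gamma(h)/sill with the map
    variance as sill; FWHM = 2 h_1/2 with rho(h_1/2) = 0.5 by linear
    interpolation between bins.  White noise reports the first bin center
    (an upper bound).
    """
    m = _as_map(surface_map)
    v = m.valid_values
    sill = v.var(ddof=0)
    if sill <= 0:
        raise ValueError("map has zero variance; FWHM undefined")
    if max_lag is None:
        max_lag = 0.5 * distances.distances.max()
    vg = variogram(m, distances, bins=bins, max_lag=max_lag)
    h, g = vg.nonempty()
    if h.size == 0:
        raise ValueError("no nonempty variogram bins")
    rho = 1.0 - g / sill
    if rho[0] <= 0.5:
        return float(h[0])
    below = np.nonzero(rho < 0.5)[0]
    if below.size == 0:
        raise ValueError("autocorrelation never crosses 0.5 within max_lag; increase max_lag")
    k = below[0]
    # linear interpolation between bins k-1 and k
    h_half = h[k - 1] + (0.5 - rho[k - 1]) * (h[k] - h[k - 1]) / (rho[k] - rho[k - 1])
    return float(2.0 * h_half)


def modal_power_spectrum(decomposition, partition) -> np.ndarray:
    """Power per eigengroup, P_L = sum over the group of beta^2.

    The constant group (index 0) is reported in place; total equals
    ||beta||^2 over the partitioned modes.
    """
    beta = decomposition.coefficients
    if partition.n_modes > beta.size:
        raise ValueError("partition spans more modes than the decomposition")
    return np.array([np.sum(beta[a:b] ** 2) for a, b in partition.slices])


def nonparametric_p(r_obs: float, null_r: np.ndarray) -> float:
    """Two-tailed surrogate p-value, p = (1 + #{|r_null| >= |r_obs|}) / (1 + S)."""
    null_r = np.asarray(null_r, dtype=np.float64)
    if null_r.size < 1:
        raise ValueError("need at least one null value")
    return float((1 + np.sum(np.abs(null_r) >= abs(r_obs))) / (1 + null_r.size))


@dataclass
class NullTest:
    """Observed statistic against a surrogate null distribution."""

    r_obs: float
    null_r: np.ndarray
    p: float
    n_surrogates: int

    @property
    def tail_count(self) -> int:
        return int(np.sum(np.abs(self.null_r) >= abs(self.r_obs)))


def null_test(y, z, surrogate_values: np.ndarray) -> NullTest:
    """Correlate z with y and with each surrogate of y (columns), returning
    the observed r, the null r distribution, and the two-tailed p."""
    r_obs = pearson_r(y, z)
    null_r = np.array([pearson_r(SurfaceMap(surrogate_values[:, s]), z)
                       for s in range(surrogate_values.shape[1])])
    return NullTest(r_obs, null_r, nonparametric_p(r_obs, null_r), null_r.size)


def fwe_correct(r_obs: np.ndarray, null_r: np.ndarray) -> np.ndarray:
    """Westfall-Young max-statistic family-wise error correction.

    `r_obs`: (T,) observed statistics; `null_r`: (T, S) nulls from the same
    shared surrogate ensemble.  Per surrogate the max |r| over targets forms
    the reference distribution; adjusted p >= unadjusted p always.
    """
    r_obs = np.atleast_1d(np.asarray(r_obs, dtype=np.float64))
    null_r = np.atleast_2d(np.asarray(null_r, dtype=np.float64))
    if null_r.shape[0] != r_obs.size:
        raise ValueError("null_r must have one row per target")
    max_stat = np.abs(null_r).max(axis=0)
    s = null_r.shape[1]
    return np.array([(1 + np.sum(max_stat >= abs(r))) / (1 + s) for r in r_obs])
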