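"""Gaussian-random-field benchmarks with tunable spatial autocorrelation.

3-D fields are synthesized spectrally: a white complex spectrum is shaped
by the amplitude filter |k|^(-alpha) and inverse-transformed, then sampled
onto a mesh by trilinear interpolation.  alpha = 0 is iid noise; larger
alpha gives smoother maps.  This amplitude exponent is calibrated so that
on the benchmark sphere the alpha = 0..3 sweep spans the regimes the
smoothness parameter is meant to cover: chance-correlation dispersion
growing steadily with alpha, autocorrelation FWHMs reaching tens of mm,
and only a handful of whole eigengroups surviving the truncation heuristic
at alpha = 3 (see docs/methods.md).  The experiment harnesses measure
false- and true-positive rates of the eigenstrapping null (or an SA-naive
vertex permutation baseline) on ensembles of field pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import binomtest

from .geometry import PairDistances, SurfaceMap, pairwise_distances
from .laplace import eigenbasis_for_mesh
from .stats import nonparametric_p, pearson_r
from .surrogates import SurrogateOptions, generate_surrogates

__all__ = [
    "GrfSpec", "ExperimentResult", "simulate_grf_volume", "sample_to_mesh",
    "simulate_grf_pair", "make_heterogeneous_pair",
    "run_fpr_experiment", "run_tpr_experiment",
]


@dataclass(frozen=True)
class GrfSpec:
    """Spectral-slope field specification on a cubic grid (mm voxels)."""

    alpha: float
    grid_n: int = 64
    voxel_size: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.grid_n < 16:
            raise ValueError("grid_n must be >= 16")


def simulate_grf_volume(spec: GrfSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Zero-mean unit-variance field with spectral amplitude ~ |k|^(-alpha)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.grid_n
    white = rng.standard_normal((n, n, n))
    spec_w = np.fft.rfftn(white)
    kx = np.fft.fftfreq(n)
    kz = np.fft.rfftfreq(n)
    k2 = kx[:, None, None] ** 2 + kx[None, :, None] ** 2 + kz[None, None, :] ** 2
    with np.errstate(divide="ignore"):
        amp = k2 ** (-spec.alpha / 2.0)  # |k|^(-alpha)
    amp[0, 0, 0] = 0.0
    fieldv = np.fft.irfftn(spec_w * amp, s=(n, n, n), axes=(0, 1, 2))
    fieldv -= fieldv.mean()
    sd = fieldv.std()
    if sd > 0:
        fieldv /= sd
    return fieldv


def sample_to_mesh(volume: np.ndarray, mesh, voxel_size: float = 1.0,
                   mask: np.ndarray | None = None,
                   pose: np.ndarray | None = None) -> SurfaceMap:
    """Trilinear interpolation of a grid field at mesh vertices (mm).

    The mesh is centered in the grid; it must fit with a >= 2-voxel margin.
    An optional keep-mask sets excluded vertices to NaN (a synthetic medial
    wall).  `pose` rotates the sampling coordinates by a 3x3 matrix: the
    periodic FFT grid has preferred (axis-aligned) directions at the lowest
    wavenumbers, and drawing a random pose per field restores the isotropy
    of the simulated ensemble.
    """
    n = volume.shape[0]
    coords = mesh.vertices if pose is None else mesh.vertices @ np.asarray(pose).T
    coords = coords / voxel_size + (n - 1) / 2.0
    if coords.min() < 2 or coords.max() > n - 3:
        raise ValueError("mesh does not fit inside the grid with a 2-voxel margin")
    vals = map_coordinates(volume, coords.T, order=1, mode="nearest")
    if mask is not None:
        vals = np.where(mask, vals, np.nan)
    return SurfaceMap(vals)


def simulate_grf_pair(alpha: float, mesh, seed: int, rho: float | None = None,
                      grid_n: int = 64, voxel_size: float = 1.0,
                      mask: np.ndarray | None = None):
    """A pair of GRF maps on a mesh; independent, or mixed to correlation rho.

    Mixing happens at the volume stage: z = rho*y + sqrt(1-rho^2)*w with w
    independent, so both maps are exchangeable fields of the same alpha.
    rho = 1 is allowed as a test hook and returns z identical to y.

    Each field is sampled at a uniformly random 3-D pose; independent pairs
    get independent poses (so they share no preferred grid orientation),
    mixed pairs share one pose (so the built-in correlation survives
    sampling).
    """
    from scipy.stats import special_ortho_group

    rng = np.random.default_rng(seed)
    spec = GrfSpec(alpha, grid_n, voxel_size)
    vy = simulate_grf_volume(spec, rng)
    vw = simulate_grf_volume(spec, rng)
    pose_y = special_ortho_group.rvs(3, random_state=rng)
    if rho is None:
        vz = vw
        pose_z = special_ortho_group.rvs(3, random_state=rng)
    else:
        if not -1.0 <= rho <= 1.0:
            raise ValueError("rho must be in [-1, 1]")
        vz = rho * vy + np.sqrt(1.0 - rho**2) * vw
        pose_z = pose_y
    y = sample_to_mesh(vy, mesh, voxel_size, mask, pose=pose_y)
    z = sample_to_mesh(vz, mesh, voxel_size, mask, pose=pose_z)
    return y, z


def make_heterogeneous_pair(alpha_low: float, alpha_high: float, mesh, seed: int,
                            grid_n: int = 64, voxel_size: float = 1.0,
                            split_axis: int = 1, mask: np.ndarray | None = None):
    """Composite map pair with different smoothness in the two mesh halves.

    Front-half vertices (positive side of `split_axis`, median split) take a
    high-alpha field, rear-half vertices a low-alpha field.  Each of the two
    returned maps is built the same way from its own independent field pair.
    """
    if not alpha_high > alpha_low:
        raise ValueError("require alpha_high > alpha_low")
    from scipy.stats import special_ortho_group

    rng = np.random.default_rng(seed)
    front = mesh.vertices[:, split_axis] >= np.median(mesh.vertices[:, split_axis])
    maps = []
    for _ in range(2):
        v_low = simulate_grf_volume(GrfSpec(alpha_low, grid_n, voxel_size), rng)
        v_high = simulate_grf_volume(GrfSpec(alpha_high, grid_n, voxel_size), rng)
        pose = special_ortho_group.rvs(3, random_state=rng)
        low = sample_to_mesh(v_low, mesh, voxel_size, mask, pose=pose)
        high = sample_to_mesh(v_high, mesh, voxel_size, mask, pose=pose)
        vals = np.where(front, high.values, low.values)
        maps.append(SurfaceMap(vals, low.mask & high.mask))
    return maps[0], maps[1]


@dataclass
class ExperimentResult:
    """FPR/TPR measurement with its exact binomial confidence interval."""

    metric: str
    value: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_surrogates: int
    alpha: float | None
    rho: float | None
    delta_alpha: float | None
    level: float
    seed: int
    n_rejected: int
    p_values: np.ndarray = field(repr=False, default=None)
    mode_counts: np.ndarray = field(repr=False, default=None)

    def to_record(self) -> dict:
        return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in [("metric", self.metric), ("value", self.value),
                             ("ci_low", self.ci_low), ("ci_high", self.ci_high),
                             ("n_pairs", self.n_pairs), ("n_surrogates", self.n_surrogates),
                             ("alpha", self.alpha), ("rho", self.rho),
                             ("delta_alpha", self.delta_alpha), ("level", self.level),
                             ("seed", self.seed), ("n_rejected", self.n_rejected)]}


def _naive_permutation_null(y: SurfaceMap, z: SurfaceMap, s: int, rng) -> float:
    joint = y.mask & z.mask
    vals = y.values[joint]
    r_obs = pearson_r(y, z)
    zz = z.values[joint]
    # SA-naive baseline: permute vertices of y
    null = np.empty(s)
    for i in range(s):
        null[i] = pearson_r(SurfaceMap(rng.permutation(vals)), SurfaceMap(zz))
    return nonparametric_p(r_obs, null)


def _pair_p_value(y, z, mesh, basis, distances, options: SurrogateOptions,
                  method: str, rng) -> tuple[float, int]:
    if method == "naive-permutation":
        return _naive_permutation_null(y, z, options.n_surrogates, rng), 0
    ens = generate_surrogates(y, basis, options, distances=distances)
    r_obs = pearson_r(y, z)
    surr = ens.values_matrix()
    zz = z.values
    mask = y.mask & z.mask
    zc = zz[mask] - zz[mask].mean()
    zn = np.sqrt(zc @ zc)
    sm = surr[mask] - surr[mask].mean(axis=0)
    null = (zc @ sm) / (np.linalg.norm(sm, axis=0) * zn)
    return nonparametric_p(r_obs, null), ens.n_modes


def _experiment(mesh, pair_factory, n_pairs, options_proto, level, seed, method,
                metric, alpha, rho, delta_alpha, n_modes_basis=None,
                distances=None) -> ExperimentResult:
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    basis = None
    if method != "naive-permutation":
        m = n_modes_basis if n_modes_basis is not None else mesh.n_vertices - 1
        basis = eigenbasis_for_mesh(mesh, m)
        if distances is None:
            distances = pairwise_distances(
                mesh, metric="geodesic",
                subsample=min(mesh.n_vertices, 256), seed=seed)
    root = np.random.SeedSequence(seed)
    pvals = np.empty(n_pairs)
    mode_counts = np.zeros(n_pairs, dtype=int)
    for i, child in enumerate(root.spawn(n_pairs)):
        pair_seed = int(child.generate_state(1)[0] % (2**31))
        y, z = pair_factory(pair_seed)
        opts = SurrogateOptions(
            n_modes=options_proto.n_modes,
            amplitude_adjust=options_proto.amplitude_adjust,
            residual_policy=options_proto.residual_policy,
            seed=pair_seed, n_surrogates=options_proto.n_surrogates)
        rng = np.random.default_rng(child)
        pvals[i], mode_counts[i] = _pair_p_value(y, z, mesh, basis, distances,
                                                 opts, method, rng)
    k = int(np.sum(pvals < level))
    ci = binomtest(k, n_pairs).proportion_ci(confidence_level=0.95, method="exact")
    return ExperimentResult(metric, k / n_pairs, float(ci.low), float(ci.high),
                            n_pairs, options_proto.n_surrogates, alpha, rho,
                            delta_alpha, level, seed, k, pvals, mode_counts)


def run_fpr_experiment(mesh, n_pairs: int, n_surrogates: int, seed: int,
                       alpha: float | None = None, delta_alpha_pair: tuple | None = None,
                       options: SurrogateOptions | None = None, level: float = 0.05,
                       method: str = "eigenstrap", grid_n: int = 64,
                       voxel_size: float = 1.0, mask: np.ndarray | None = None,
                       distances: PairDistances | None = None) -> ExperimentResult:
    """False-positive rate of a null method on independent GRF pairs.

    Either `alpha` (homogeneous fields) or `delta_alpha_pair`
    = (alpha_low, alpha_high) (front/rear composite fields) must be given.
    `method` is 'eigenstrap' or the SA-naive 'naive-permutation' baseline.
    """
    if (alpha is None) == (delta_alpha_pair is None):
        raise ValueError("give exactly one of alpha or delta_alpha_pair")
    if options is None:
        options = SurrogateOptions(n_surrogates=n_surrogates)
    else:
        options.n_surrogates = n_surrogates
    if delta_alpha_pair is not None:
        lo, hi = delta_alpha_pair
        factory = lambda s: make_heterogeneous_pair(lo, hi, mesh, s, grid_n, voxel_size, mask=mask)
        d_alpha = hi - lo
    else:
        factory = lambda s: simulate_grf_pair(alpha, mesh, s, rho=None,
                                              grid_n=grid_n, voxel_size=voxel_size, mask=mask)
        d_alpha = None
    return _experiment(mesh, factory, n_pairs, options, level, seed, method,
                       "FPR", alpha, None, d_alpha, distances=distances)


def run_tpr_experiment(mesh, alpha: float, rho: float, n_pairs: int,
                       n_surrogates: int, seed: int,
                       options: SurrogateOptions | None = None, level: float = 0.05,
                       grid_n: int = 64, voxel_size: float = 1.0,
                       mask: np.ndarray | None = None,
                       distances: PairDistances | None = None) -> ExperimentResult:
    """True-positive rate on GRF pairs with a fixed built-in correlation."""
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    if options is None:
        options = SurrogateOptions(n_surrogates=n_surrogates)
    else:
        options.n_surrogates = n_surrogates
    factory = lambda s: simulate_grf_pair(alpha, mesh, s, rho=rho,
                                          grid_n=grid_n, voxel_size=voxel_size, mask=mask)
    return _experiment(mesh, factory, n_pairs, options, level, seed,
                       "eigenstrap", "TPR", alpha, rho, None, distances=distances)
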