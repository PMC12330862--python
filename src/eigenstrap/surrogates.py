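"""Surrogate map generation by random rotation of eigengroups.

A map y on a mesh is decomposed onto LBO eigenmodes, y = Psi beta + eps.
Eigenmodes are partitioned by index into groups of sizes 1, 3, 5, ... —
the spherical-harmonic multiplicities 2L+1 — which on a sphere share one
eigenvalue and hence one spatial wavelength.  Each rotatable group is mapped
to its degenerate spherical representation by the elementwise scaling
kappa = lambda^(-1/2), rotated by an independent Haar-random orthogonal
matrix, and mapped back with zeta = lambda^(1/2).  Reconstructing with the
original coefficients yields a surrogate with the original map's spatial
autocorrelation but randomized alignment; the residual is permuted (or
zeroed) and an optional rank-order amplitude adjustment restores the exact
value distribution of the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ortho_group

from .geometry import PairDistances, SurfaceMap
from .laplace import EigenBasis

__all__ = [
    "EigenGroupPartition", "Decomposition", "SurrogateOptions", "SurrogateEnsemble",
    "partition_eigengroups", "decompose", "random_rotation", "rotate_groups",
    "generate_surrogates", "amplitude_adjust", "choose_n_modes", "mode_set_fraction",
]


@dataclass(frozen=True)
class EigenGroupPartition:
    """Contiguous index ranges of sizes 2L+1 with per-mode normalizers.

    kappa = lambda^(-1/2) and zeta = lambda^(1/2) map each group onto / back
    from the degenerate sphere; xi is the nominal common eigenvalue of a
    group after normalization (its mean eigenvalue).  The constant group
    (L=0, lambda=0) is flagged non-rotatable.
    """

    slices: tuple            # per-group (start, stop)
    group_numbers: np.ndarray
    kappa: np.ndarray        # per mode; nan on the constant mode
    zeta: np.ndarray         # per mode
    xi: np.ndarray           # per group
    n_modes: int             # modes covered (sum of group sizes)
    n_dropped: int

    @property
    def n_groups(self) -> int:
        return len(self.slices)

    def rotatable(self):
        for g, (a, b) in enumerate(self.slices):
            if self.group_numbers[g] > 0:
                yield g, a, b


def partition_eigengroups(basis: EigenBasis) -> EigenGroupPartition:
    """Assign ascending-eigenvalue modes to groups of sizes 1, 3, 5, ..."""
    lam = basis.eigenvalues
    m = len(lam)
    if m < 4:
        raise ValueError("need at least 4 modes for one rotatable eigengroup")
    if np.any(np.diff(lam) < -1e-12 * max(lam.max(), 1e-300)):
        raise ValueError("eigenvalues must be ascending")
    slices, numbers = [], []
    start, lam_group = 0, 0
    while start + 2 * lam_group + 1 <= m:
        size = 2 * lam_group + 1
        slices.append((start, start + size))
        numbers.append(lam_group)
        start += size
        lam_group += 1
    dropped = m - start
    if dropped:
        warnings.warn(f"{dropped} trailing modes do not complete an eigengroup; dropped")
    with np.errstate(divide="ignore"):
        kappa = lam[:start] ** -0.5
    kappa[0] = np.nan  # constant mode, lambda = 0
    zeta = lam[:start] ** 0.5
    xi = np.array([lam[a:b].mean() for a, b in slices])
    return EigenGroupPartition(tuple(slices), np.asarray(numbers), kappa, zeta, xi,
                               n_modes=start, n_dropped=dropped)


@dataclass
class Decomposition:
    """Modal coefficients and per-vertex residual of a map."""

    coefficients: np.ndarray
    residual: np.ndarray      # nan outside the mask
    mask: np.ndarray
    n_modes: int
    method: str               # 'mass-inner-product' | 'least-squares'


def decompose(surface_map: SurfaceMap, basis: EigenBasis, n_modes: int | None = None) -> Decomposition:
    """Fit a map with the first `n_modes` eigenmodes.

    Fully valid maps use the mass inner product beta = Psi^T B y (the exact
    adjoint of reconstruction).  Masked maps fit beta by ordinary least
    squares on the valid vertices, since the mass inner product would read
    data under the mask.
    """
    if n_modes is None:
        n_modes = basis.n_modes
    if surface_map.n_vertices != basis.modes.shape[0]:
        raise ValueError("map length does not match basis vertex count")
    n_modes = min(n_modes, basis.n_modes)
    psi = basis.modes[:, :n_modes]
    mask = surface_map.mask
    if mask.all():
        y = surface_map.values
        beta = psi.T @ (basis.mass @ y)
        method = "mass-inner-product"
    else:
        if mask.sum() < n_modes:
            raise ValueError(f"only {int(mask.sum())} valid vertices for {n_modes} modes")
        y = surface_map.values.copy()
        beta, *_ = np.linalg.lstsq(psi[mask], y[mask], rcond=None)
        method = "least-squares"
    residual = np.full(surface_map.n_vertices, np.nan)
    residual[mask] = surface_map.values[mask] - psi[mask] @ beta
    return Decomposition(beta, residual, mask, n_modes, method)


def random_rotation(n: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform orthogonal matrix on O(n); n=1 gives ±1."""
    if n < 1:
        raise ValueError("dimension must be >= 1")
    if n == 1:
        return np.array([[rng.choice([-1.0, 1.0])]])
    return ortho_group.rvs(n, random_state=rng)


def _rotated_coefficients(beta, partition, rng):
    """Coefficient-space rotation: c_L = diag(kappa) R_L diag(zeta) beta_L.

    Psi' beta == Psi c, so rotating coefficients avoids forming Psi'.
    """
    c = beta.copy()
    for g, a, b in partition.rotatable():
        r = random_rotation(b - a, rng)
        c[a:b] = partition.kappa[a:b] * (r @ (partition.zeta[a:b] * beta[a:b]))
    return c


def rotate_groups(basis: EigenBasis, partition: EigenGroupPartition,
                  rng: np.random.Generator, rotations=None) -> np.ndarray:
    """Rotated mode matrix Psi' with an independent rotation per group.

    Per rotatable group: Psi'_L = (Psi_L ⊙ kappa_L) R_L ⊙ zeta_L, the zeta
    ordering following the group's original index order.  The constant group
    passes through unrotated.  `rotations` overrides the random draws
    (used by tests and the identity path).
    """
    if partition.n_modes > basis.n_modes:
        raise ValueError("partition does not belong to this basis")
    if np.any(basis.eigenvalues[1:partition.n_modes] <= 0):
        raise ValueError("zero eigenvalue inside a rotatable group; kappa undefined")
    psi = basis.modes[:, :partition.n_modes].copy()
    for g, a, b in partition.rotatable():
        r = rotations[g] if rotations is not None else random_rotation(b - a, rng)
        psi[:, a:b] = (psi[:, a:b] * partition.kappa[a:b]) @ r * partition.zeta[a:b]
    return psi


@dataclass
class SurrogateOptions:
    """Knobs of the surrogate generator.

    n_modes=None triggers the FWHM heuristic (requires `distances`);
    residual_policy is 'permute' (default) or 'zero'; amplitude adjustment
    rank-remaps each surrogate onto the original value distribution.
    """

    n_modes: int | None = None
    amplitude_adjust: bool = True
    residual_policy: str = "permute"
    seed: int = 0
    n_surrogates: int = 1

    def __post_init__(self):
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.residual_policy not in ("permute", "zero"):
            raise ValueError(f"unknown residual_policy {self.residual_policy!r}")


@dataclass
class SurrogateEnsemble:
    maps: list                # of SurfaceMap
    options: SurrogateOptions
    n_modes: int
    basis_id: str
    child_seeds: np.ndarray   # per-surrogate seeds derived from options.seed

    def __len__(self):
        return len(self.maps)

    def values_matrix(self) -> np.ndarray:
        """(n_vertices, S) matrix of surrogate values (nan under the mask)."""
        return np.column_stack([m.values for m in self.maps])


def amplitude_adjust(surrogate: np.ndarray, original: np.ndarray,
                     mask: np.ndarray | None = None) -> np.ndarray:
    """Rank-order remap: k-th smallest surrogate value := k-th smallest
    original value.  Ties broken by vertex index (stable argsort)."""
    surrogate = np.asarray(surrogate, dtype=np.float64)
    original = np.asarray(original, dtype=np.float64)
    if mask is None:
        mask = np.isfinite(surrogate) & np.isfinite(original)
    s, o = surrogate[mask], original[mask]
    if s.size != o.size:
        raise ValueError("valid-vertex counts differ")
    out = np.full(surrogate.shape, np.nan)
    order = np.argsort(s, kind="stable")
    adj = np.empty_like(s)
    adj[order] = np.sort(o)
    tmp = out.copy()
    tmp[mask] = adj
    return tmp


def choose_n_modes(surface_map: SurfaceMap, basis: EigenBasis,
                   partition: EigenGroupPartition, distances: PairDistances) -> int:
    """Whole-group mode count from the map's spatial smoothness.

    A group's characteristic scale is its nominal wavelength,
    2 pi / sqrt(mean lambda); every whole group whose scale is at least the
    map's estimated FWHM is kept, and at least one rotatable group is always
    kept.  A single group's own autocorrelation FWHM is about half its
    wavelength, so comparing the full wavelength against the map FWHM keeps
    groups down to half the map's summary scale — a one-octave guard band
    that matters for multiscale (power-law) maps, where a substantial
    variance fraction lies below the summary FWHM and would otherwise be
    whitened by the residual permutation, narrowing the null.
    """
    from .stats import estimate_fwhm

    try:
        fwhm_map = estimate_fwhm(surface_map, distances)
    except ValueError as err:
        if "cross" in str(err):
            # autocorrelation never decays to 0.5 within max_lag: the map is
            # at least that smooth, so act as if the FWHM were the window
            fwhm_map = 2.0 * distances.distances.max()
        else:
            raise
    with np.errstate(divide="ignore"):
        fwhm_groups = 2.0 * np.pi / np.sqrt(partition.xi)
    keep = fwhm_groups >= fwhm_map
    keep[:2] = True  # constant group plus at least one rotatable group
    # groups are ordered coarse->fine; keep the contiguous coarse run
    last = int(np.nonzero(keep)[0].max())
    while not keep[:last + 1].all():
        last -= 1
    return int(partition.slices[last][1])


def mode_set_fraction(n_modes: int, n_vertices: int) -> float:
    """Truncation depth as a percentage of the complete surface-mode set."""
    return 100.0 * n_modes / n_vertices


def generate_surrogates(surface_map: SurfaceMap, basis: EigenBasis,
                        options: SurrogateOptions,
                        distances: PairDistances | None = None,
                        _identity_ops: bool = False) -> SurrogateEnsemble:
    """Generate an ensemble of SA-preserving surrogates of one map.

    Each surrogate draws fresh independent rotations per eigengroup, adds a
    permuted (or zero) residual over valid vertices, and optionally applies
    amplitude adjustment last.  Fully determined by (options.seed, index).
    ``_identity_ops`` replaces every rotation and permutation with the
    identity — a hook for exactness checks.
    """
    if surface_map.n_vertices != basis.modes.shape[0]:
        raise ValueError("map length does not match basis")
    partition_full = partition_eigengroups(basis)
    if options.n_modes is None:
        if distances is None:
            raise ValueError("auto n_modes requires a distance structure")
        n_modes = choose_n_modes(surface_map, basis, partition_full, distances)
    else:
        n_modes = min(options.n_modes, partition_full.n_modes)
        # truncate down to whole groups
        stops = np.array([b for _, b in partition_full.slices])
        if n_modes not in stops:
            n_new = int(stops[stops <= n_modes].max())
            warnings.warn(f"n_modes={n_modes} does not span whole groups; truncated to {n_new}")
            n_modes = n_new
    if n_modes < 4:
        raise ValueError("fewer than 4 modes; no rotatable group")
    if np.any(basis.eigenvalues[1:n_modes] <= 0):
        raise ValueError("zero eigenvalue inside a rotatable group; kappa undefined")
    partition = partition_eigengroups(basis.subset(n_modes))

    dec = decompose(surface_map, basis, n_modes)
    mask = dec.mask
    psi_valid = basis.modes[mask, :n_modes]
    eps_valid = dec.residual[mask]

    root = np.random.SeedSequence(options.seed)
    children = root.spawn(options.n_surrogates)
    child_seeds = np.array([c.generate_state(1)[0] % (2**31) for c in children], dtype=np.int64)

    coef_cols = np.empty((n_modes, options.n_surrogates))
    eps_cols = np.empty((mask.sum(), options.n_surrogates))
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        if _identity_ops:
            coef_cols[:, s] = dec.coefficients
            eps_cols[:, s] = eps_valid if options.residual_policy == "permute" else 0.0
            continue
        coef_cols[:, s] = _rotated_coefficients(dec.coefficients, partition, rng)
        if options.residual_policy == "permute":
            eps_cols[:, s] = rng.permutation(eps_valid)
        else:
            eps_cols[:, s] = 0.0
    recon = psi_valid @ coef_cols + eps_cols

    maps = []
    for s in range(options.n_surrogates):
        vals = np.full(surface_map.n_vertices, np.nan)
        vals[mask] = recon[:, s]
        if options.amplitude_adjust:
            vals = amplitude_adjust(vals, surface_map.values, mask)
        maps.append(SurfaceMap(vals, mask.copy()))
    return SurrogateEnsemble(maps, options, n_modes, basis.mesh_id, child_seeds)
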