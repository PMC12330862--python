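"""Eigengroup partitioning, rotation, and surrogate generation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eigenstrap as es
from eigenstrap.surrogates import _rotated_coefficients


class TestPartition:
    def test_sizes_one_three_five(self, basis3):
        part = es.partition_eigengroups(es.EigenBasis(
            basis3.modes[:, :16], basis3.eigenvalues[:16], basis3.mass,
            basis3.boundary_tag, basis3.mesh_id))
        assert [b - a for a, b in part.slices] == [1, 3, 5, 7]
        assert part.n_dropped == 0

    def test_incomplete_group_dropped(self, basis3):
        part = es.partition_eigengroups(es.EigenBasis(
            basis3.modes[:, :18], basis3.eigenvalues[:18], basis3.mass,
            basis3.boundary_tag, basis3.mesh_id))
        assert part.n_modes == 16
        assert part.n_dropped == 2

    def test_index_groups_match_eigenvalue_clusters(self, basis3):
        """On the sphere, index-based groups coincide with the clusters found
        by an independent gap-based detection."""
        lam = basis3.eigenvalues[:36]
        gaps = np.diff(lam)
        # a cluster boundary is a gap much larger than within-cluster spread
        boundaries = [i + 1 for i, g in enumerate(gaps) if g > 0.05 * max(lam[i + 1], 1)]
        part = es.partition_eigengroups(basis3)
        starts = [a for a, _ in part.slices if a < 36][1:]
        assert boundaries[: len(starts)] == starts

    def test_kappa_zeta_inverse(self, basis3):
        part = es.partition_eigengroups(basis3)
        prod = part.kappa[1:] * part.zeta[1:]
        assert np.abs(prod - 1.0).max() < 1e-12

    def test_too_few_modes_rejected(self, basis3):
        small = es.EigenBasis(basis3.modes[:, :3], basis3.eigenvalues[:3],
                              basis3.mass, basis3.boundary_tag, basis3.mesh_id)
        with pytest.raises(ValueError, match="at least 4"):
            es.partition_eigengroups(small)

    @given(m=st.integers(min_value=4, max_value=200))
    @settings(max_examples=20, deadline=None)
    def test_slices_tile_without_overlap(self, basis3, m):
        basis = es.EigenBasis(basis3.modes[:, :m], basis3.eigenvalues[:m],
                              basis3.mass, basis3.boundary_tag, basis3.mesh_id)
        part = es.partition_eigengroups(basis)
        covered = np.concatenate([np.arange(a, b) for a, b in part.slices])
        assert np.array_equal(covered, np.arange(part.n_modes))
        assert part.n_modes + part.n_dropped == m


class TestDecompose:
    def test_full_basis_residual_vanishes(self, basis3, rng):
        y = es.SurfaceMap(rng.standard_normal(basis3.modes.shape[0]))
        dec = es.decompose(y, basis3)
        res = np.linalg.norm(dec.residual) / np.linalg.norm(y.values)
        assert res < 1e-6

    def test_single_mode_recovered(self, basis3):
        y = es.SurfaceMap(3.0 * basis3.modes[:, 5])
        dec = es.decompose(y, basis3, 16)
        assert dec.coefficients[5] == pytest.approx(3.0, abs=1e-8)
        others = np.delete(dec.coefficients, 5)
        assert np.abs(others).max() < 1e-8

    def test_masked_fit_matches_normal_equations(self, sphere1, rng):
        basis = es.eigenbasis_for_mesh(sphere1, 16)
        vals = rng.standard_normal(42)
        vals[:5] = np.nan
        y = es.SurfaceMap(vals)
        dec = es.decompose(y, basis, 9)
        psi = basis.modes[y.mask, :9]
        beta_oracle = np.linalg.solve(psi.T @ psi, psi.T @ vals[y.mask])
        assert np.allclose(dec.coefficients, beta_oracle, atol=1e-10)
        assert dec.method == "least-squares"

    def test_rank_error_when_too_masked(self, sphere1):
        basis = es.eigenbasis_for_mesh(sphere1, 16)
        vals = np.full(42, np.nan)
        vals[:10] = 1.0
        with pytest.raises(ValueError, match="valid vertices"):
            es.decompose(es.SurfaceMap(vals), basis, 16)


class TestRandomRotation:
    def test_orthogonality(self, rng):
        for n in (1, 2, 3, 7):
            r = es.random_rotation(n, rng)
            assert np.abs(r.T @ r - np.eye(n)).max() < 1e-10

    def test_one_dimensional_gives_signs(self, rng):
        draws = {float(es.random_rotation(1, rng)[0, 0]) for _ in range(50)}
        assert draws == {-1.0, 1.0}

    def test_haar_mean_zero(self):
        rng = np.random.default_rng(11)
        total = np.zeros((3, 3))
        n = 10000
        for _ in range(n):
            total += es.random_rotation(3, rng)
        se = 1.0 / np.sqrt(3 * n)  # column entries have variance 1/3
        assert np.abs(total / n).max() < 3 * se

    def test_first_column_uniform_on_sphere(self):
        """z-coordinate of a uniform point on S^2 is uniform on [-1, 1]."""
        from scipy.stats import kstest, uniform

        rng = np.random.default_rng(5)
        z = np.array([es.random_rotation(3, rng)[2, 0] for _ in range(10000)])
        assert kstest(z, uniform(loc=-1, scale=2).cdf).pvalue > 0.01


class TestRotateGroups:
    def test_identity_rotations_reproduce_modes(self, basis3):
        part = es.partition_eigengroups(basis3.subset(16))
        rotations = {g: np.eye(b - a) for g, a, b in part.rotatable()}
        psi = es.rotate_groups(basis3, part, None, rotations=rotations)
        assert np.allclose(psi, basis3.modes[:, :16], atol=0)

    def test_rotated_modes_stay_orthonormal_on_sphere(self, basis3, rng):
        # restrict to L <= 2, whose degeneracy is exact on the icosphere
        # (icosahedral symmetry); kappa and zeta are then constant per group
        part = es.partition_eigengroups(basis3.subset(9))
        psi = es.rotate_groups(basis3, part, rng)
        gram = psi.T @ (basis3.mass @ psi)
        assert np.abs(gram - np.eye(9)).max() < 1e-8

    def test_group_projector_invariant(self, basis3, rng):
        """The normalized group projector Psi_L diag(kappa^2) Psi_L^T B is
        unchanged by rotation on the sphere."""
        part = es.partition_eigengroups(basis3.subset(16))
        psi = es.rotate_groups(basis3, part, rng)
        for g, a, b in part.rotatable():
            k2 = part.kappa[a:b] ** 2
            before = (basis3.modes[:, a:b] * k2) @ basis3.modes[:, a:b].T @ basis3.mass
            after = (psi[:, a:b] * k2) @ psi[:, a:b].T @ basis3.mass
            assert np.abs(before - after).max() < 1e-8


class TestAmplitudeAdjust:
    def test_multiset_equality(self, rng):
        s, o = rng.standard_normal(100), rng.standard_normal(100)
        adj = es.amplitude_adjust(s, o)
        assert np.array_equal(np.sort(adj), np.sort(o))

    def test_monotone_remap(self, rng):
        from scipy.stats import spearmanr

        s, o = rng.standard_normal(200), rng.standard_normal(200)
        adj = es.amplitude_adjust(s, o)
        assert spearmanr(s, adj).statistic == pytest.approx(1.0)

    def test_idempotent(self, rng):
        s, o = rng.standard_normal(64), rng.standard_normal(64)
        once = es.amplitude_adjust(s, o)
        twice = es.amplitude_adjust(once, o)
        assert np.array_equal(once, twice)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_histogram_preserved_under_any_seed(self, seed):
        r = np.random.default_rng(seed)
        s, o = r.standard_normal(30), r.standard_normal(30)
        assert np.array_equal(np.sort(es.amplitude_adjust(s, o)), np.sort(o))


class TestGenerateSurrogates:
    def test_identity_operations_reproduce_input(self, basis3, rng):
        y = es.SurfaceMap(rng.standard_normal(basis3.modes.shape[0]))
        opts = es.SurrogateOptions(n_modes=16, amplitude_adjust=False,
                                   residual_policy="permute", seed=0, n_surrogates=1)
        ens = es.generate_surrogates(y, basis3, opts, _identity_ops=True)
        assert np.allclose(ens.maps[0].values, y.values, atol=1e-10)

    def test_deterministic_in_seed(self, basis3, rng):
        y = es.SurfaceMap(rng.standard_normal(basis3.modes.shape[0]))
        opts = es.SurrogateOptions(n_modes=25, seed=42, n_surrogates=3)
        a = es.generate_surrogates(y, basis3, opts)
        b = es.generate_surrogates(y, basis3, opts)
        assert np.array_equal(a.values_matrix(), b.values_matrix())
        c = es.generate_surrogates(y, basis3, es.SurrogateOptions(
            n_modes=25, seed=43, n_surrogates=3))
        assert not np.array_equal(a.values_matrix(), c.values_matrix())

    def test_per_group_power_conserved_on_sphere(self, basis3, rng):
        """Exactly degenerate groups (L <= 2 are protected by icosahedral
        symmetry): recomputed surrogate coefficients are a rotation of the
        originals, so per-group power is conserved."""
        y = es.SurfaceMap(rng.standard_normal(basis3.modes.shape[0]))
        opts = es.SurrogateOptions(n_modes=9, amplitude_adjust=False,
                                   residual_policy="zero", seed=7, n_surrogates=5)
        ens = es.generate_surrogates(y, basis3, opts)
        dec = es.decompose(y, basis3, 9)
        part = es.partition_eigengroups(basis3.subset(9))
        p_orig = es.modal_power_spectrum(dec, part)
        for m in ens.maps:
            dec_s = es.decompose(m, basis3, 9)
            p_surr = es.modal_power_spectrum(dec_s, part)
            assert np.abs(p_surr[1:] - p_orig[1:]).max() < 1e-8 * p_orig[1:].max()

    def test_rotated_coefficients_norm_preserved_under_degeneracy(self, basis3, rng):
        part = es.partition_eigengroups(basis3.subset(9))
        beta = rng.standard_normal(9)
        c = _rotated_coefficients(beta, part, rng)
        for _, a, b in part.rotatable():
            assert np.linalg.norm(c[a:b]) == pytest.approx(np.linalg.norm(beta[a:b]))

    def test_masked_region_never_receives_values(self, sphere3, rng):
        keep = es.polar_cap_mask(sphere3, cap_fraction=0.2)
        vals = rng.standard_normal(sphere3.n_vertices)
        vals[~keep] = np.nan
        y = es.SurfaceMap(vals)
        basis = es.eigenbasis_for_mesh(sphere3, 100)
        opts = es.SurrogateOptions(n_modes=25, seed=3, n_surrogates=4)
        ens = es.generate_surrogates(y, basis, opts)
        for m in ens.maps:
            assert np.array_equal(m.mask, y.mask)
            assert np.all(np.isnan(m.values[~keep]))
            assert np.all(np.isfinite(m.values[keep]))

    def test_gaussianization_without_amplitude_adjust(self, basis3, rng):
        """A skewed input map yields surrogates with skewness shrinking toward
        0 (Central Limit behavior of the randomized modal sum); amplitude
        adjustment instead restores the original value multiset."""
        from scipy.stats import skew

        raw = rng.standard_normal(basis3.modes.shape[0])
        y = es.SurfaceMap(np.exp(raw))  # lognormal: strongly right-skewed
        s_in = skew(y.values)
        opts = es.SurrogateOptions(n_modes=100, amplitude_adjust=False,
                                   residual_policy="zero", seed=1, n_surrogates=20)
        ens = es.generate_surrogates(y, basis3, opts)
        s_out = np.mean([skew(m.values) for m in ens.maps])
        assert abs(s_out) < 0.5 * abs(s_in)
        opts_adj = es.SurrogateOptions(n_modes=100, amplitude_adjust=True,
                                       residual_policy="zero", seed=1, n_surrogates=3)
        for m in es.generate_surrogates(y, basis3, opts_adj).maps:
            assert np.array_equal(np.sort(m.values), np.sort(y.values))

    def test_truncation_to_whole_groups_warns(self, basis3, rng):
        y = es.SurfaceMap(rng.standard_normal(basis3.modes.shape[0]))
        opts = es.SurrogateOptions(n_modes=20, seed=0, n_surrogates=1)
        with pytest.warns(UserWarning, match="whole groups"):
            ens = es.generate_surrogates(y, basis3, opts)
        assert ens.n_modes == 16


class TestChooseNModes:
    def test_white_noise_selects_near_full_basis(self, sphere3, basis3, dist3, rng):
        part = es.partition_eigengroups(basis3)
        noise = es.SurfaceMap(rng.standard_normal(sphere3.n_vertices))
        n = es.choose_n_modes(noise, basis3, part, dist3)
        assert n == part.n_modes  # every whole group of the basis

    def test_single_coarse_mode_selects_few_groups(self, sphere3, basis3, dist3, rng):
        y = es.SurfaceMap(basis3.modes[:, 5] + 1e-3 * rng.standard_normal(sphere3.n_vertices))
        n = es.choose_n_modes(y, basis3, part := es.partition_eigengroups(basis3), dist3)
        assert n <= 36  # a few groups only

    def test_monotone_in_smoothness(self, sphere3_r28, basis3_r28, dist3_r28):
        part = es.partition_eigengroups(basis3_r28)
        counts = []
        for alpha in (0.0, 1.5, 3.0):
            y, _ = es.simulate_grf_pair(alpha, sphere3_r28, seed=99)
            counts.append(es.choose_n_modes(y, basis3_r28, part, dist3_r28))
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[0] > counts[2]

    def test_constant_map_rejected(self, sphere3, basis3, dist3):
        flat = es.SurfaceMap(np.ones(sphere3.n_vertices))
        part = es.partition_eigengroups(basis3)
        with pytest.raises(ValueError, match="variance"):
            es.choose_n_modes(flat, basis3, part, dist3)


def test_mode_set_fraction_matches_reported_truncation():
    """6,000 modes on a 32,492-vertex hemisphere is 18.5% of the complete
    surface-mode set."""
    assert round(es.mode_set_fraction(6000, 32492), 1) == 18.5
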