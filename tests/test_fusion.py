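import numpy as np
import pytest

from conftest import smooth_field
from wildfuse import fusion as F
from wildfuse.fusion.pyramid import build_laplacian_pyramid, reconstruct_pyramid
from wildfuse.fusion.sparse import dct_dictionary, omp_code
from wildfuse.fusion.variational import (
    SolverDivergence,
    fuse_tvm,
    poisson_solve_neumann,
    tvm_energy,
)
from wildfuse.fusion.wavelet import _decompose, _reconstruct, _weighted_coeffs, fuse_wl_swarm
from wildfuse.quality import petrovic_metric, region_entropy

IDENTITY_TOL = {m: 1e-3 for m in F.METHOD_NAMES} | {"sparse": 1e-2}


@pytest.fixture(scope="module")
def a_img():
    return smooth_field(0, (96, 112), blur=3.0)


@pytest.fixture(scope="module")
def b_img():
    return smooth_field(1, (96, 112), blur=4.0)


class TestDispatch:
    @pytest.mark.parametrize("method", F.METHOD_NAMES)
    def test_identity_fusion(self, method, a_img):
        res = F.fuse(F.FusionInput(a=a_img, b=a_img), method, seed=1)
        assert np.abs(res.fused - a_img).max() <= IDENTITY_TOL[method]

    @pytest.mark.parametrize("method", F.METHOD_NAMES)
    def test_bounded_and_dimension_preserving(self, method, a_img, b_img):
        res = F.fuse(F.FusionInput(a=a_img, b=b_img), method, seed=1)
        assert res.fused.shape == a_img.shape
        assert res.fused.min() >= 0.0 and res.fused.max() <= 1.0

    @pytest.mark.parametrize("method", F.METHOD_NAMES)
    def test_deterministic(self, method, a_img, b_img):
        inp = F.FusionInput(a=a_img, b=b_img)
        f1 = F.fuse(inp, method, seed=3).fused
        f2 = F.fuse(inp, method, seed=3).fused
        assert np.array_equal(f1, f2)

    def test_unknown_method_rejected(self, a_img):
        with pytest.raises(ValueError, match="unknown fusion method"):
            F.fuse(F.FusionInput(a=a_img, b=a_img), "neural")

    def test_dims_mismatch_rejected(self, a_img):
        with pytest.raises(ValueError):
            F.FusionInput(a=a_img, b=a_img[:-1])

    def test_nan_rejected(self, a_img):
        bad = a_img.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            F.FusionInput(a=a_img, b=bad)


class TestLuminanceAndNormalize:
    def test_gray_pixel_passthrough(self):
        rgb = np.full((4, 4, 3), 0.42)
        assert np.allclose(F.to_luminance(rgb), 0.42)

    def test_pure_blue_coefficient(self):
        rgb = np.zeros((2, 2, 3))
        rgb[..., 2] = 1.0
        assert np.allclose(F.to_luminance(rgb), 0.114)

    def test_convexity(self):
        rgb = np.random.default_rng(0).uniform(0, 1, (16, 16, 3))
        lum = F.to_luminance(rgb)
        assert (lum >= rgb.min(axis=2) - 1e-12).all()
        assert (lum <= rgb.max(axis=2) + 1e-12).all()

    def test_wrong_channel_count(self):
        with pytest.raises(ValueError):
            F.to_luminance(np.zeros((4, 4, 4)))

    def test_normalize_constant_to_zeros(self):
        assert np.array_equal(F.normalize_intensity(np.full((5, 5), 3.0)), np.zeros((5, 5)))

    def test_normalize_affine_invariance(self):
        x = np.random.default_rng(1).uniform(0, 1, (12, 12))
        assert np.allclose(F.normalize_intensity(x), F.normalize_intensity(2.5 * x + 7.0))

    def test_normalize_unit_range_unchanged(self):
        x = np.linspace(0, 1, 64).reshape(8, 8)
        assert np.allclose(F.normalize_intensity(x), x)


class TestLaplacianPyramid:
    def test_exact_reconstruction(self, a_img):
        stack = build_laplacian_pyramid(a_img, levels=4)
        assert np.abs(reconstruct_pyramid(stack) - a_img).max() <= 1e-6

    def test_step_edge_preserved(self):
        """A step edge fused against a flat image keeps its edge: the
        Petrovic score of the fused output stays near perfect."""
        a = np.zeros((64, 64))
        a[:, 32:] = 1.0
        b = np.full((64, 64), 0.5)
        fused = F.fuse_laplacian(a, b)
        assert petrovic_metric(a, b, fused) >= 0.9

    def test_symmetric_inputs_symmetric_output(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0.1, 0.9, (32, 32))
        b = rng.uniform(0.1, 0.9, (32, 32))
        f_ab = F.fuse_laplacian(a, b, levels=2, block=4)
        f_ba = F.fuse_laplacian(b, a, levels=2, block=4)
        assert np.abs(f_ab - f_ba).max() <= 1e-12

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            F.fuse_laplacian(np.zeros((8, 8)), np.zeros((8, 8)), levels=4)


class TestGuidedFilter:
    def test_salient_source_dominates(self):
        """When one source carries all the texture and the other is flat,
        the fused image follows the textured source."""
        a = smooth_field(2, (96, 96), blur=1.0)
        b = np.full((96, 96), float(a.mean()))
        fused = F.fuse_guided_filter(a, b)
        assert np.abs(fused - a).max() <= 5e-2

    def test_parameter_validation(self):
        a = np.zeros((16, 16))
        with pytest.raises(ValueError):
            F.fuse_guided_filter(a, a, r_base=0)
        with pytest.raises(ValueError):
            F.fuse_guided_filter(a, a, eps_base=0.0)


class TestSVD:
    def test_textured_beats_constant(self):
        a = smooth_field(3, (32, 32), blur=1.0)
        b = np.full((32, 32), 0.2)
        fused = F.fuse_svd(a, b, block=8)
        assert np.array_equal(fused, np.clip(a, 0, 1))

    def test_blockwise_selection_property(self):
        """Every fused block equals one source block or their mean."""
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, (24, 24))
        b = rng.uniform(0, 1, (24, 24))
        fused = F.fuse_svd(a, b, block=8)
        for r in range(0, 24, 8):
            for c in range(0, 24, 8):
                fb = fused[r : r + 8, c : c + 8]
                ab = a[r : r + 8, c : c + 8]
                bb = b[r : r + 8, c : c + 8]
                assert (
                    np.allclose(fb, ab)
                    or np.allclose(fb, bb)
                    or np.allclose(fb, 0.5 * (ab + bb))
                )


class TestSparse:
    def test_dictionary_unit_norm(self):
        d = dct_dictionary(8, 256)
        assert d.shape == (64, 256)
        assert np.allclose(np.linalg.norm(d, axis=0), 1.0)

    def test_omp_residual_nonincreasing(self):
        d = dct_dictionary(8, 256)
        sig = smooth_field(6, (8, 8)).reshape(64, 1)
        sig = sig - sig.mean()
        residuals = []
        for k in range(1, 9):
            code = omp_code(d, sig, max_atoms=k)
            residuals.append(np.linalg.norm(sig - d @ code))
        assert all(r2 <= r1 + 1e-12 for r1, r2 in zip(residuals, residuals[1:]))

    def test_larger_l1_code_wins_single_patch(self):
        """Single-patch oracle: fusing a textured image with a flat one at
        non-overlapping patches reproduces each textured patch's own sparse
        reconstruction (the flat patches code to zero and lose the L1 contest)."""
        d = dct_dictionary(8, 256)
        textured = smooth_field(7, (16, 16), blur=0.5)
        flat = np.full((16, 16), 0.5)
        fused = F.fuse_sparse(textured, flat, patch=8, stride=8)
        for r in range(0, 16, 8):
            for c in range(0, 16, 8):
                patch = textured[r : r + 8, c : c + 8]
                code = omp_code(d, (patch - patch.mean()).reshape(64, 1))
                recon = (d @ code).reshape(8, 8) + patch.mean()
                assert np.abs(fused[r : r + 8, c : c + 8] - np.clip(recon, 0, 1)).max() <= 1e-9

    def test_unnormalized_dictionary_rejected(self):
        bad = dct_dictionary(8, 256) * 2.0
        with pytest.raises(ValueError):
            omp_code(bad, np.zeros((64, 1)))


class TestGradientFusion:
    def test_constant_partner_recovers_source(self, a_img):
        b = np.full_like(a_img, 0.5)
        fused = F.fuse_gradient(a_img, b)
        expected = np.clip(a_img - a_img.mean() + 0.5 * (a_img.mean() + 0.5), 0, 1)
        assert np.abs(fused - expected).max() <= 1e-3

    def test_poisson_recovers_cosine_eigenfunction(self):
        """Integrating the analytic gradient field of cos(pi x) cos(pi y)
        (sampled on the DCT grid, in per-pixel units) reproduces the field
        to discretization accuracy."""
        n = 256
        x = (np.arange(n) + 0.5) / n
        f_true = np.cos(np.pi * x)[:, None] * np.cos(np.pi * x)[None, :]
        xh = (np.arange(n) + 1.0) / n  # forward-difference sample points
        h = 1.0 / n
        gx = -np.pi * np.sin(np.pi * xh)[None, :] * np.cos(np.pi * x)[:, None] * h
        gy = -np.pi * np.sin(np.pi * xh)[:, None] * np.cos(np.pi * x)[None, :] * h
        gx[:, -1] = 0.0
        gy[-1, :] = 0.0
        rec = poisson_solve_neumann(gx, gy, mean=float(f_true.mean()))
        assert np.abs(rec - f_true).max() <= 1e-4


class TestTVM:
    def test_small_lambda_tracks_thermal(self, a_img, b_img):
        fused = fuse_tvm(a_img, b_img, lam=1e-4, iters=20)
        assert np.abs(fused - b_img).max() <= 1e-3

    def test_identity_attains_zero_energy(self, a_img):
        fused, energies = fuse_tvm(a_img, a_img, return_energy=True)
        assert np.abs(fused - a_img).max() <= 1e-6
        # residual energy is the eps-smoothing floor only
        assert energies[-1] <= 1e-5 * a_img.size

    def test_energy_trace_monotone_and_consistent(self, a_img, b_img):
        fused, energies = fuse_tvm(a_img, b_img, iters=40, return_energy=True)
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(energies, energies[1:]))
        # the recorded final energy matches direct evaluation on the
        # pre-clipping minimizer within clipping tolerance
        direct = tvm_energy(fused, a_img, b_img, lam=4.0)
        assert direct == pytest.approx(energies[-1], rel=1e-2)

    def test_invalid_lambda(self, a_img):
        with pytest.raises(ValueError):
            fuse_tvm(a_img, a_img, lam=0.0)


class TestWavelets:
    def test_perfect_reconstruction_without_merge(self, a_img):
        coeffs = _decompose(a_img, "db2", 3)
        rec = _reconstruct(coeffs, "db2", a_img.shape)
        assert np.abs(rec - a_img).max() <= 1e-6

    def test_wl_tvm_detail_max_abs_rule(self, a_img, b_img):
        ca = _decompose(a_img, "db2", 2)
        cb = _decompose(b_img, "db2", 2)
        from wildfuse.fusion.wavelet import _max_abs

        for ta, tb in zip(ca[1:], cb[1:]):
            for da, db in zip(ta, tb):
                merged = _max_abs(da, db)
                # at non-tied coefficients the magnitude equals the larger source
                nt = np.abs(np.abs(da) - np.abs(db)) > 1e-12
                assert np.allclose(
                    np.abs(merged[nt]), np.maximum(np.abs(da), np.abs(db))[nt]
                )

    def test_too_small_for_levels(self):
        with pytest.raises(ValueError):
            F.fuse_wl_tvm(np.zeros((8, 8)), np.zeros((8, 8)), levels=5)


class TestSwarm:
    def test_objective_trace_nondecreasing(self, a_img, b_img):
        _, _, trace = fuse_wl_swarm(a_img, b_img, seed=2, return_details=True)
        assert all(t2 >= t1 for t1, t2 in zip(trace, trace[1:]))

    def test_noise_source_attracts_approximation_weight(self):
        """With a high-entropy noise partner, the optimizer moves the
        approximation weight strongly toward that source; a 0.01-resolution
        grid search over a uniform weight confirms the direction and level."""
        a = np.tile(np.linspace(0.3, 0.7, 96), (96, 1))
        b = np.random.default_rng(5).uniform(0, 1, (96, 96))
        fused, weights, trace = fuse_wl_swarm(a, b, seed=7, return_details=True)
        assert weights[0] <= 0.5 - 0.2  # moved >= 0.2 toward the noise source

        ca = _decompose(a, "db2", 3)
        cb = _decompose(b, "db2", 3)
        grid_vals = []
        for w in np.arange(0.0, 1.0001, 0.01):
            rec = _reconstruct(_weighted_coeffs(ca, cb, np.full(10, w)), "db2", a.shape)
            grid_vals.append((region_entropy(np.clip(rec, 0, 1)), w))
        best_val, best_w = max(grid_vals)
        assert best_w <= 0.3  # grid search agrees the noise source should dominate
        assert trace[-1] >= best_val - 0.05

    def test_swarm_size_validation(self, a_img):
        with pytest.raises(ValueError):
            fuse_wl_swarm(a_img, a_img, swarm_size=1, seed=0)


class TestEdgePreservation:
    EDGE_PRESERVING = tuple(m for m in F.METHOD_NAMES if m != "wl_swarm")

    @pytest.mark.parametrize("method", EDGE_PRESERVING)
    @pytest.mark.parametrize("seeds", [(0, 1), (2, 3)])
    def test_beats_naive_averaging(self, method, seeds):
        """Where each modality carries its own texture — the regime fusion is
        for — every transform- or optimization-based merge preserves edges at
        least as well as plain 50/50 averaging, which halves the gradient of
        any structure unique to one source. The entropy-driven swarm hybrid
        is excluded: its objective rewards information content, not edge
        contrast. Asserted for these seeds, not claimed universally."""
        a = smooth_field(seeds[0], (96, 112), blur=2.0)
        b = smooth_field(seeds[1], (96, 112), blur=2.0)
        fused = F.fuse(F.FusionInput(a=a, b=b), method, seed=2).fused
        q_avg = petrovic_metric(a, b, 0.5 * (a + b))
        assert petrovic_metric(a, b, fused) >= q_avg


class TestLearnedDictionary:
    def test_seed_required_and_deterministic(self):
        from wildfuse.fusion.sparse import learned_dictionary

        img = smooth_field(9, (48, 48), blur=2.0)
        with pytest.raises(ValueError):
            learned_dictionary(img)
        d1 = learned_dictionary(img, seed=3, iters=2)
        d2 = learned_dictionary(img, seed=3, iters=2)
        assert np.array_equal(d1, d2)
        assert d1.shape == (64, 256)
        assert np.allclose(np.linalg.norm(d1, axis=0), 1.0)
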