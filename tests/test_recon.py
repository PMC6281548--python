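"""OSEM reconstruction: EM fixed point, likelihood ascent, background
correction oracles, post-filtering."""

import warnings

import numpy as np
import pytest

import spillrecon as sr
from spillrecon.recon import _bit_reversed_order


@pytest.fixture(scope="module")
def random_system(small_grid, small_model):
    rng = np.random.default_rng(1)
    x = rng.random(small_grid.shape)
    M = 0.5 + 0.5 * rng.random(small_model.sinogram_shape)
    A = 0.1 * np.ones(small_model.sinogram_shape)
    y = M * small_model.forward(x) + A
    return {"x": x, "M": M, "A": A, "y": y}


class TestOsemCore:
    def test_truth_is_fixed_point_of_noise_free_update(
        self, small_model, random_system, psf42
    ):
        """With y = M H'x + A and f0 = x the EM multiplier is exactly 1."""
        ss = sr.SinogramSet(
            y=random_system["y"],
            M=random_system["M"],
            A=random_system["A"],
            geometry=small_model.geometry,
        )
        cfg = sr.ReconConfig(
            variant="OSEM_PSF", n_subsets=4, n_full_iterations=3, psf=psf42
        )
        res = sr.osem_reconstruct(ss, small_model, cfg, initial=random_system["x"])
        assert np.allclose(res.final_unfiltered, random_system["x"], atol=1e-12)

    def test_likelihood_nondecreasing_single_subset(
        self, small_model, random_system, psf42
    ):
        """MLEM (1 subset) monotonically increases the Poisson likelihood."""
        rng = np.random.default_rng(2)
        y = rng.poisson(random_system["y"] * 20).astype(float)
        ss = sr.SinogramSet(
            y=y,
            M=random_system["M"] * 20,
            A=random_system["A"] * 20,
            geometry=small_model.geometry,
        )
        cfg = sr.ReconConfig(
            variant="OSEM_PSF", n_subsets=1, n_full_iterations=15, psf=psf42
        )
        res = sr.osem_reconstruct(ss, small_model, cfg)
        diffs = np.diff(res.loglik)
        assert np.all(diffs >= -1e-8)

    def test_iterates_nonnegative_and_counts_conserved(self, small_model):
        """MLEM with M=1, A=0 preserves total counts every full iteration."""
        model = small_model.with_psf(None)
        rng = np.random.default_rng(3)
        x = rng.random(model.grid.shape)
        y = rng.poisson(model.forward(x) * 10).astype(float)
        ss = sr.SinogramSet(
            y=y,
            M=np.ones(model.sinogram_shape),
            A=np.zeros(model.sinogram_shape),
            geometry=model.geometry,
        )
        cfg = sr.ReconConfig(
            variant="OSEM", n_subsets=1, n_full_iterations=5, save_every=1
        )
        res = sr.osem_reconstruct(ss, model, cfg)
        for it, img in res.images.items():
            assert np.all(img >= 0)
            fitted = model.forward(img).sum()
            assert abs(fitted - y.sum()) <= 1e-8 * y.sum()

    def test_variant_validation(self, psf42):
        with pytest.raises(ValueError, match="no PSF"):
            sr.ReconConfig(variant="OSEM", psf=psf42)
        with pytest.raises(ValueError, match="requires a PSF"):
            sr.ReconConfig(variant="OSEM_PSF")
        with pytest.raises(ValueError, match="BackgroundSpec"):
            sr.ReconConfig(variant="OSEM_PSF_BC", psf=psf42)
        with pytest.raises(ValueError, match="unknown variant"):
            sr.ReconConfig(variant="FBP")
        cfg = sr.ReconConfig(variant="osem+psf", psf=psf42)
        assert cfg.variant == "OSEM_PSF"

    def test_subsets_must_divide_views(self, small_model, random_system, psf42):
        ss = sr.SinogramSet(
            y=random_system["y"],
            M=random_system["M"],
            A=random_system["A"],
            geometry=small_model.geometry,
        )
        cfg = sr.ReconConfig(
            variant="OSEM_PSF", n_subsets=5, n_full_iterations=1, psf=psf42
        )
        with pytest.raises(ValueError, match="divide"):
            sr.osem_reconstruct(ss, small_model, cfg)

    def test_bit_reversed_order_is_permutation(self):
        for n in (1, 2, 7, 28):
            order = _bit_reversed_order(n)
            assert sorted(order) == list(range(n))


class TestBackgroundCorrection:
    def test_exact_cancellation(self, small_model, bladder_box_problem, psf42):
        """Bladder-only data with exact P reconstructs to ~zero (28 subsets,
        50 iterations, L-inf below 1e-3 x bladder SUV)."""
        prob = bladder_box_problem
        bc = sr.BackgroundSpec(prob["mask"], precomputed_P=prob["P_exact"])
        cfg = sr.ReconConfig(
            variant="OSEM_PSF_BC",
            n_subsets=28,
            n_full_iterations=50,
            psf=psf42,
            bc=bc,
            track_loglik=False,
        )
        res = sr.osem_reconstruct(prob["sinos"], small_model, cfg)
        assert res.final_unfiltered.max() < 1e-3 * prob["suv"]

    def test_empty_mask_degenerates_to_psf_recon(
        self, small_model, random_system, psf42
    ):
        ss = sr.SinogramSet(
            y=random_system["y"],
            M=random_system["M"],
            A=random_system["A"],
            geometry=small_model.geometry,
        )
        bc = sr.BackgroundSpec(np.zeros(small_model.grid.shape, dtype=bool))
        with pytest.warns(UserWarning, match="empty hot mask"):
            P = sr.make_background_term(
                bc,
                ss,
                small_model,
                sr.ReconConfig(variant="OSEM_PSF_BC", n_subsets=4,
                               n_full_iterations=2, psf=psf42, bc=bc),
            )
        assert np.all(P == 0)
        cfg_bc = sr.ReconConfig(
            variant="OSEM_PSF_BC",
            n_subsets=4,
            n_full_iterations=3,
            psf=psf42,
            bc=sr.BackgroundSpec(np.zeros(small_model.grid.shape, dtype=bool),
                                 precomputed_P=P),
        )
        cfg_psf = sr.ReconConfig(
            variant="OSEM_PSF", n_subsets=4, n_full_iterations=3, psf=psf42
        )
        a = sr.osem_reconstruct(ss, small_model, cfg_bc).final_unfiltered
        b = sr.osem_reconstruct(ss, small_model, cfg_psf).final_unfiltered
        assert np.array_equal(a, b)

    def test_full_support_mask_recovers_all_counts(
        self, small_model, random_system, psf42
    ):
        """With the mask covering everything and N large, P -> y - A."""
        ss = sr.SinogramSet(
            y=random_system["y"],
            M=random_system["M"],
            A=random_system["A"],
            geometry=small_model.geometry,
        )
        bc = sr.BackgroundSpec(
            np.ones(small_model.grid.shape, dtype=bool), source_recon_iterations=60
        )
        cfg = sr.ReconConfig(
            variant="OSEM_PSF_BC", n_subsets=28, n_full_iterations=1, psf=psf42,
            bc=bc, track_loglik=False,
        )
        P = sr.make_background_term(bc, ss, small_model, cfg)
        target = ss.y - ss.A
        rel = np.linalg.norm(P - target) / np.linalg.norm(target)
        assert rel < 0.01

    def test_background_term_tracks_true_bladder_counts(self, tiny_pelvic):
        """P from the 5-iteration source stays within 20% of the true
        bladder's projected counts."""
        phantom = tiny_pelvic["phantom"]
        model = tiny_pelvic["model"]
        ss = tiny_pelvic["sinos"][0]
        mask = sr.region_mask(phantom, "bladder")
        bc = sr.BackgroundSpec(mask, source_recon_iterations=5)
        cfg = sr.ReconConfig(
            variant="OSEM_PSF_BC",
            n_subsets=4,
            n_full_iterations=1,
            psf=model.psf,
            bc=bc,
            track_loglik=False,
        )
        P = sr.make_background_term(bc, ss, model, cfg)
        bladder_true = np.where(mask, phantom.suv_image, 0.0)
        P_true = ss.M * model.forward(bladder_true)
        assert abs(P.sum() - P_true.sum()) / P_true.sum() < 0.20

    def test_bc_equivalent_to_presubtraction_on_noise_free_data(
        self, small_model, psf42
    ):
        """Reconstructing y with BC matches plain reconstruction of y - P in
        the lesion ROI after convergence (within 1%)."""
        grid = small_model.grid
        bladder = np.zeros(grid.shape)
        bladder[8:18, 8:18] = 40.0
        lesion = np.zeros(grid.shape)
        lesion[22:26, 22:26] = 8.0
        truth = bladder + lesion
        mask = bladder > 0
        M = np.full(small_model.sinogram_shape, 0.8)
        A = np.full(small_model.sinogram_shape, 0.05)
        P = M * small_model.forward(bladder)
        y = M * small_model.forward(truth) + A
        ss_bc = sr.SinogramSet(y=y, M=M, A=A, geometry=small_model.geometry)
        ss_sub = sr.SinogramSet(
            y=np.maximum(y - P, 0.0), M=M, A=A, geometry=small_model.geometry
        )
        cfg_bc = sr.ReconConfig(
            variant="OSEM_PSF_BC", n_subsets=28, n_full_iterations=100, psf=psf42,
            bc=sr.BackgroundSpec(mask, precomputed_P=P), track_loglik=False,
        )
        cfg_sub = sr.ReconConfig(
            variant="OSEM_PSF", n_subsets=28, n_full_iterations=100, psf=psf42,
            track_loglik=False,
        )
        f_bc = sr.osem_reconstruct(ss_bc, small_model, cfg_bc).final_unfiltered
        f_sub = sr.osem_reconstruct(ss_sub, small_model, cfg_sub).final_unfiltered
        roi = lesion > 0
        assert abs(f_bc[roi].mean() - f_sub[roi].mean()) / f_sub[roi].mean() < 0.01


class TestPostFilter:
    def test_identity_and_mass(self, small_grid):
        rng = np.random.default_rng(9)
        img = rng.random(small_grid.shape)
        assert np.array_equal(sr.post_filter(img, 0.0, small_grid), img)
        out = sr.post_filter(img, 4.0, small_grid)
        assert abs(out.sum() - img.sum()) < 1e-9 * img.sum()

    def test_filter_never_feeds_back(self, small_model, random_system, psf42):
        ss = sr.SinogramSet(
            y=random_system["y"],
            M=random_system["M"],
            A=random_system["A"],
            geometry=small_model.geometry,
        )
        kw = dict(variant="OSEM_PSF", n_subsets=4, n_full_iterations=3, psf=psf42)
        plain = sr.osem_reconstruct(
            ss, small_model, sr.ReconConfig(**kw, post_filter_fwhm_mm=None)
        )
        filt = sr.osem_reconstruct(
            ss, small_model, sr.ReconConfig(**kw, post_filter_fwhm_mm=4.0)
        )
        assert np.array_equal(plain.final_unfiltered, filt.final_unfiltered)
        assert np.array_equal(
            filt.final,
            sr.post_filter(filt.final_unfiltered, 4.0, small_model.grid),
        )
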