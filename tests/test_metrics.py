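"""SUV statistics, percent change, shell analysis and CNR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spillrecon as sr
from spillrecon.metrics import roi_mask


@pytest.fixture(scope="module")
def flat_grid():
    return sr.ImageGrid((20, 20), (2.0, 2.0))


@pytest.fixture(scope="module")
def centre_roi():
    return sr.ROISpec((0.0, 0.0), 10.0, "L")


def _images_with_roi_values(grid, roi, values):
    mask = roi_mask(roi, grid)
    out = []
    for v in values:
        img = np.zeros(grid.shape)
        img[mask] = v
        out.append(img)
    return out


class TestSUVStats:
    def test_hand_computed_summary(self, flat_grid, centre_roi):
        """Four realisations {7,8,9,8}: mean 8, SD 0.8165, SEM 0.4082."""
        imgs = _images_with_roi_values(flat_grid, centre_roi, [7, 8, 9, 8])
        st = sr.suv_stats(imgs, centre_roi, true_suv=8.0, grid=flat_grid)
        assert st.mean_max == 8.0
        assert st.sd_max == pytest.approx(0.816497, abs=1e-6)
        assert st.sem_max == pytest.approx(0.408248, abs=1e-6)
        assert st.bias_max == pytest.approx(0.0, abs=1e-12)

    def test_bias_from_printed_mean(self, flat_grid, centre_roi):
        """ROI mean of 8.08 against truth 8 is a bias of exactly 1.00%."""
        imgs = _images_with_roi_values(flat_grid, centre_roi, [8.08, 8.08])
        st = sr.suv_stats(imgs, centre_roi, true_suv=8.0, grid=flat_grid)
        assert st.bias_max == pytest.approx(1.00, abs=1e-10)
        assert st.sd_max == 0.0 and st.sem_max == 0.0

    def test_max_at_least_mean_on_random_images(self, flat_grid, centre_roi):
        rng = np.random.default_rng(0)
        imgs = [rng.random(flat_grid.shape) for _ in range(6)]
        st = sr.suv_stats(imgs, centre_roi, true_suv=1.0, grid=flat_grid)
        assert np.all(st.suv_max >= st.suv_mean)

    def test_internal_consistency(self, flat_grid, centre_roi):
        """SEM and bias are recomputable from the stored per-realisation
        values (n-1 denominator)."""
        rng = np.random.default_rng(1)
        imgs = [rng.random(flat_grid.shape) for _ in range(9)]
        st = sr.suv_stats(imgs, centre_roi, true_suv=0.5, grid=flat_grid)
        assert st.sem_max == pytest.approx(
            np.std(st.suv_max, ddof=1) / 3.0, rel=1e-12
        )
        assert st.bias_mean == pytest.approx(
            (np.mean(st.suv_mean) - 0.5) / 0.5 * 100, rel=1e-12
        )

    def test_roi_outside_grid_rejected(self, flat_grid):
        with pytest.raises(ValueError, match="no voxel centres"):
            sr.suv_stats(
                [np.zeros(flat_grid.shape)],
                sr.ROISpec((500.0, 0.0), 4.0, "far"),
                1.0,
                flat_grid,
            )


class TestSUVChange:
    @pytest.mark.parametrize(
        "lo,hi,expect",
        [(8.0, 10.0, 25.0), (3.3, 3.3, 0.0), (7.30, 9.54, 30.6849)],
    )
    def test_percent_change(self, lo, hi, expect):
        # the third case is the proximal-lesion change recomputed from
        # rounded two-decimal table entries (30.68 vs 30.67 from unrounded)
        assert sr.suv_change(lo, hi) == pytest.approx(expect, abs=5e-3)

    def test_zero_reference(self):
        with pytest.raises(ZeroDivisionError):
            sr.suv_change(0.0, 5.0)


def brute_force_shells(mask, n_max, step):
    """Oracle: per-voxel Euclidean distance thresholding against every mask
    voxel (no distance transform)."""
    pts = np.argwhere(mask)
    grid_pts = np.indices(mask.shape).reshape(mask.ndim, -1).T
    d2 = ((grid_pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1).min(1)
    dist = np.sqrt(d2).reshape(mask.shape)
    shells = []
    prev = 0
    for hi in range(step, n_max + 1, step):
        shells.append((dist > prev) & (dist <= hi) & ~mask)
        prev = hi
    return shells


class TestShells:
    def test_single_voxel_ball_1(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[3, 3, 3] = True
        shells = sr.dilate_shells(mask, n_max=1, step=1)
        assert int(shells[0][1].sum()) == 6  # face neighbours only in 3D

    @pytest.mark.parametrize("seed,ndim", [(0, 2), (1, 2), (2, 3)])
    def test_matches_brute_force(self, seed, ndim):
        rng = np.random.default_rng(seed)
        shape = (18, 18) if ndim == 2 else (10, 10, 10)
        mask = np.zeros(shape, dtype=bool)
        idx = tuple(rng.integers(4, s - 4) for s in shape)
        mask[idx] = True
        mask[tuple(min(i + 1, s - 1) for i, s in zip(idx, shape))] = True
        shells = sr.dilate_shells(mask, n_max=4, step=2)
        oracle = brute_force_shells(mask, 4, 2)
        for (rng_, got), want in zip(shells, oracle):
            assert np.array_equal(got, want), rng_

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_masks_match_brute_force(self, seed):
        """Property: distance-transform shells equal explicit Euclidean
        thresholding for arbitrary sparse masks."""
        rng = np.random.default_rng(seed)
        mask = rng.random((12, 12)) < 0.12
        if not mask.any():
            mask[6, 6] = True
        shells = sr.dilate_shells(mask, n_max=4, step=2)
        oracle = brute_force_shells(mask, 4, 2)
        for (_, got), want in zip(shells, oracle):
            assert np.array_equal(got, want)

    def test_telescoping_union_and_disjointness(self):
        mask = np.zeros((24, 24), dtype=bool)
        mask[10:14, 10:14] = True
        shells = sr.dilate_shells(mask, n_max=6, step=2)
        union = mask.copy()
        seen = np.zeros_like(mask)
        from scipy import ndimage

        for _, s in shells:
            assert not (s & mask).any()
            assert not (s & seen).any()
            seen |= s
            union |= s
        dist = ndimage.distance_transform_edt(~mask)
        assert np.array_equal(union, (dist <= 6) | mask)

    def test_sphere_shell_counts_increase(self):
        grid = sr.ImageGrid((40, 40), (2.0, 2.0))
        X, Y = grid.coordinate_images()
        mask = X**2 + Y**2 <= 10.0**2
        shells = sr.dilate_shells(mask, n_max=6, step=2)
        counts = [int(s.sum()) for _, s in shells]
        assert counts[0] < counts[1] < counts[2]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sr.dilate_shells(np.zeros((5, 5), dtype=bool), 2, 1)


class TestShellSpillAnalysis:
    def _toy(self):
        true = np.zeros((9, 9))
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        true[mask] = 100.0
        return true, mask

    def test_identical_images_give_zero(self):
        true, mask = self._toy()
        shells = sr.dilate_shells(mask, 2, 2)
        sa = sr.shell_spill_analysis(true, true.copy(), mask, shells)
        assert sa.d_bar == [0.0] and sa.sd == [0.0]
        assert sa.loa == [(0.0, 0.0)]

    def test_hand_built_loa(self):
        """d_k = {10, 20, 30}% gives d-bar 20, SD 10, LOA [0.4, 39.6]."""
        true, mask = self._toy()
        recon = true.copy()
        shell = np.zeros_like(mask)
        shell[3, 4] = shell[5, 4] = shell[4, 3] = True
        recon[3, 4] += 10.0
        recon[5, 4] += 20.0
        recon[4, 3] += 30.0
        sa = sr.shell_spill_analysis(
            true, recon, mask, [((1, 1), shell)], reference_value=100.0
        )
        assert sa.d_bar[0] == pytest.approx(20.0)
        assert sa.sd[0] == pytest.approx(10.0)
        assert sa.loa[0][0] == pytest.approx(0.4)
        assert sa.loa[0][1] == pytest.approx(39.6)

    def test_matches_naive_recomputation(self):
        rng = np.random.default_rng(4)
        true, mask = self._toy()
        true += rng.random(true.shape)
        recon = true + rng.normal(0, 5, true.shape)
        shells = sr.dilate_shells(mask, 4, 2)
        sa = sr.shell_spill_analysis(true, recon, mask, shells)
        ref = true[mask].mean()
        for (rng_, shell), db, sd in zip(shells, sa.d_bar, sa.sd):
            d_k = (recon[shell] - true[shell]) / ref * 100
            assert db == pytest.approx(d_k.mean(), rel=1e-12)
            n = d_k.size
            assert sd == pytest.approx(
                np.sqrt(((d_k - d_k.mean()) ** 2).sum() / (n - 1)), rel=1e-12
            )

    def test_per_voxel_normalisation_flag(self):
        true, mask = self._toy()
        true += 2.0
        recon = true * 1.5
        shells = sr.dilate_shells(mask, 2, 2)
        sa = sr.shell_spill_analysis(
            true, recon, mask, shells, normalisation="true_voxel"
        )
        assert sa.d_bar[0] == pytest.approx(50.0)
        with pytest.raises(ValueError, match="unknown normalisation"):
            sr.shell_spill_analysis(true, recon, mask, shells, normalisation="x")


class TestCNR:
    def test_hand_values(self):
        img = np.array([10 - 3, 10 - 3, 10.0, 10 + 3, 10 + 3,
                        2 - 4, 2 - 4, 2.0, 2 + 4, 2 + 4])
        sphere = np.zeros(10, dtype=bool)
        sphere[:5] = True
        back = ~sphere
        rep = sr.cnr(sphere, back, img)
        assert rep.cnr == pytest.approx(8.0 / 5.0)
        assert rep.mean_sphere == 10.0 and rep.mean_background == 2.0

    def test_equal_means_zero_and_degenerate_raises(self):
        img = np.array([5.0, 5.0, 5.0, 6.0])
        sphere = np.array([True, True, False, False])
        assert sr.cnr(sphere, ~sphere, np.array([5.0, 7.0, 5.0, 7.0])).cnr == 0.0
        with pytest.raises(ZeroDivisionError):
            sr.cnr(sphere, ~sphere, np.array([1.0, 1.0, 2.0, 2.0]))


def test_write_suv_csv(tmp_path):
    import csv

    path = str(tmp_path / "suv.csv")
    rows = [
        {"variant": "OSEM", "lesion": "L3", "suv_max": 9.54, "bias_percent": 19.27},
        {"variant": "OSEM_PSF_BC", "lesion": "L3", "suv_max": 8.1,
         "bias_percent": 1.2},
    ]
    sr.metrics.write_suv_csv(path, rows)
    with open(path) as fh:
        back = list(csv.DictReader(fh))
    assert back[0]["lesion"] == "L3" and float(back[1]["suv_max"]) == 8.1
    with pytest.raises(ValueError, match="no rows"):
        sr.metrics.write_suv_csv(path, [])


class TestNormalisedShellActivity:
    def test_raw_and_zero_cases(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        img = np.zeros((9, 9))
        shells = sr.dilate_shells(mask, 2, 2)
        assert sr.normalised_shell_activity(img, mask, shells, 3.0) == [0.0]
        img += 2.0
        assert sr.normalised_shell_activity(img, mask, shells, 1.0) == [2.0]
        with pytest.raises(ValueError, match="reference"):
            sr.normalised_shell_activity(img, mask, shells, 0.0)
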