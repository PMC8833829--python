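import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnbcpet import features as ft
from tnbcpet.imaging import ValidationError
from tnbcpet.segmentation import LesionMask, threshold_voi

from _oracles import (
    glcm_bruteforce,
    glrlm_bruteforce,
    glszm_bruteforce,
    peak_sphere_mean,
)
from conftest import suv_from_array


def mask_all(shape):
    m = np.ones(shape, dtype=bool)
    return LesionMask(mask=m, component_id=1, voxel_count=int(m.sum()))


def mask_from(arr):
    m = np.asarray(arr, dtype=bool)
    return LesionMask(mask=m, component_id=1, voxel_count=int(m.sum()))


def random_dvoi(rng, shape=(4, 4, 4), levels=6):
    """A random small discretized VOI (~70% coverage) for oracle comparisons."""
    labels = rng.integers(1, levels + 1, size=shape).astype(np.int16)
    labels[rng.random(shape) < 0.3] = 0
    if (labels > 0).sum() == 0:
        labels[0, 0, 0] = 1
    return ft.DiscretizedVoi(labels=labels, levels=levels)


class TestSuvStatistics:
    def test_constant_field(self):
        suv = suv_from_array(np.full((10, 10, 10), 5.0), spacing=(4, 4, 4))
        smax, smean, speak = ft.suv_statistics(suv, mask_all((10, 10, 10)))
        assert smax == smean == speak == 5.0

    def test_peak_sphere_hand_case(self):
        # One SUV-10 voxel among SUV 4 at 4 mm isotropic: the 1 cm^3 sphere
        # (radius 6.2035 mm) covers the 19 voxels with center distance <= radius.
        grid = np.full((9, 9, 9), 4.0)
        grid[4, 4, 4] = 10.0
        suv = suv_from_array(grid, spacing=(4, 4, 4))
        smax, _, speak = ft.suv_statistics(suv, mask_all((9, 9, 9)))
        oracle_mean, oracle_count = peak_sphere_mean(grid, (4, 4, 4), (4, 4, 4))
        assert smax == 10.0
        assert oracle_count == 19
        assert speak == pytest.approx((10.0 + 18 * 4.0) / 19)
        assert speak == pytest.approx(oracle_mean)

    def test_peak_includes_out_of_mask_voxels(self):
        # Hot single-voxel mask near cold background: peak averages background in.
        grid = np.full((9, 9, 9), 1.0)
        grid[4, 4, 4] = 10.0
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[4, 4, 4] = True
        suv = suv_from_array(grid, spacing=(4, 4, 4))
        _, _, speak = ft.suv_statistics(suv, mask_from(mask))
        assert speak == pytest.approx((10.0 + 18 * 1.0) / 19)

    def test_peak_matches_exhaustive_oracle_random(self, rng):
        grid = rng.uniform(0, 10, size=(7, 7, 7))
        spacing = (3.0, 4.0, 5.0)
        suv = suv_from_array(grid, spacing=spacing)
        mask = mask_all((7, 7, 7))
        center = np.unravel_index(np.argmax(grid), grid.shape)
        oracle_mean, _ = peak_sphere_mean(grid, spacing, center)
        assert ft.suv_peak(suv, mask) == pytest.approx(oracle_mean)

    def test_mean_is_masked_average(self, rng):
        grid = rng.uniform(0, 9, size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.4
        mask[0, 0, 0] = True
        suv = suv_from_array(grid)
        _, smean, _ = ft.suv_statistics(suv, mask_from(mask))
        assert smean == pytest.approx(grid[mask].sum() / mask.sum())


class TestVolumeAndTlg:
    def test_mtv_hand_values(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m.flat[:100] = True
        assert ft.metabolic_volume(mask_from(m), (4, 4, 4)) == pytest.approx(6.4)
        single = np.zeros((2, 2, 2), dtype=bool)
        single[0, 0, 0] = True
        assert ft.metabolic_volume(mask_from(single), (10, 10, 10)) == pytest.approx(1.0)

    def test_mtv_spacing_scaling(self, rng):
        m = rng.random((5, 5, 5)) < 0.5
        m[0, 0, 0] = True
        lm = mask_from(m)
        assert ft.metabolic_volume(lm, (4, 4, 4)) == pytest.approx(
            8 * ft.metabolic_volume(lm, (2, 2, 2))
        )

    def test_tlg_is_product(self, rng):
        assert ft.total_lesion_glycolysis(5.0, 10.0) == 50.0
        for _ in range(20):
            a, b = rng.uniform(0.1, 30, size=2)
            assert ft.total_lesion_glycolysis(a, b) == a * b

    def test_extracted_mean_at_least_threshold(self):
        # With SUV2.5 segmentation every VOI voxel is >= 2.5, so SUVmean >= 2.5.
        rng = np.random.default_rng(3)
        grid = rng.uniform(0, 8, size=(8, 8, 8))
        suv = suv_from_array(grid)
        for m in threshold_voi(suv):
            assert grid[m.mask].mean() >= 2.5


class TestDiscretization:
    @pytest.mark.parametrize(
        "value,level",
        [(0.0, 1), (20.0, 64), (35.0, 64), (2.5, 9), (0.3124, 1), (0.3125, 2)],
    )
    def test_bin_rule_hand_values(self, value, level):
        grid = np.full((2, 2, 2), value)
        dvoi = ft.discretize_voi(suv_from_array(grid), mask_all((2, 2, 2)))
        assert int(dvoi.labels[0, 0, 0]) == level

    def test_exhaustive_bin_edges(self):
        # 10,000 values across 0..25 SUV: label must follow the closed form
        # 1 + floor(v / 0.3125) with clipping to level 64 at v >= 20.
        values = np.linspace(0.0, 25.0, 10_000)
        grid = values.reshape((10, 10, 100))
        dvoi = ft.discretize_voi(suv_from_array(grid), mask_all(grid.shape))
        expected = np.minimum(1 + np.floor(np.minimum(values, 20.0) / 0.3125).astype(int), 64)
        np.testing.assert_array_equal(dvoi.labels.reshape(-1), expected)

    def test_outside_mask_is_zero(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        dvoi = ft.discretize_voi(suv_from_array(np.full((3, 3, 3), 5.0)), mask_from(m))
        assert dvoi.labels[1, 1, 1] > 0 and dvoi.labels.sum() == dvoi.labels[1, 1, 1]

    @given(a=st.floats(0.0, 30.0), b=st.floats(0.0, 30.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_in_suv(self, a, b):
        lo, hi = min(a, b), max(a, b)
        grid = np.array([lo, hi]).reshape(2, 1, 1)
        dvoi = ft.discretize_voi(suv_from_array(grid), mask_all((2, 1, 1)))
        assert dvoi.labels[0, 0, 0] <= dvoi.labels[1, 0, 0]

    @pytest.mark.parametrize("kwargs", [dict(max_suv=0.0), dict(levels=1)])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValidationError):
            ft.discretize_voi(
                suv_from_array(np.ones((2, 2, 2))), mask_all((2, 2, 2)), **kwargs
            )


class TestGlcm:
    def test_two_voxel_voi_single_entry(self):
        labels = np.zeros((2, 1, 1), dtype=np.int16)
        labels[:, 0, 0] = 3
        glcm = ft.build_glcm(ft.DiscretizedVoi(labels=labels, levels=4))
        assert glcm[2, 2] == 1.0 and glcm.sum() == 1.0

    def test_constant_voi_diagonal(self):
        labels = np.full((3, 3, 3), 5, dtype=np.int16)
        glcm = ft.build_glcm(ft.DiscretizedVoi(labels=labels, levels=8))
        assert glcm[4, 4] == 1.0

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            dvoi = random_dvoi(rng)
            np.testing.assert_allclose(
                ft.build_glcm(dvoi), glcm_bruteforce(dvoi.labels, dvoi.levels), atol=1e-12
            )

    def test_homogeneity_closed_forms(self):
        assert ft.glcm_homogeneity(np.eye(4) / 4) == 1.0
        for k in (1, 2, 5):
            two = np.zeros((8, 8))
            two[0, k] = two[k, 0] = 0.5
            assert ft.glcm_homogeneity(two) == pytest.approx(1 / (1 + k))

    def test_entropy_closed_forms(self):
        constant = np.zeros((4, 4))
        constant[1, 1] = 1.0
        assert ft.glcm_entropy(constant) == 0.0
        four = np.zeros((4, 4))
        four[[0, 0, 1, 1], [0, 1, 0, 1]] = 0.25
        assert ft.glcm_entropy(four) == pytest.approx(2.0)


class TestGlrlm:
    def test_alternating_line_all_runs_length_one(self):
        labels = np.array([1, 2, 1, 2], dtype=np.int16).reshape(4, 1, 1)
        glrlm = ft.build_glrlm(ft.DiscretizedVoi(labels=labels, levels=2))
        assert glrlm.shape[1] == 1  # no run longer than 1
        assert ft.glrlm_sre(glrlm) == 1.0 and ft.glrlm_lre(glrlm) == 1.0

    def test_single_straight_run(self):
        labels = np.full((4, 1, 1), 3, dtype=np.int16)
        glrlm = ft.build_glrlm(ft.DiscretizedVoi(labels=labels, levels=4))
        # one length-4 run along x; each of the other 12 directions sees 4 singletons
        assert glrlm[2, 3] == 1
        assert glrlm[2, 0] == 48

    def test_matches_line_scan_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            dvoi = random_dvoi(rng)
            np.testing.assert_array_equal(
                ft.build_glrlm(dvoi), glrlm_bruteforce(dvoi.labels, dvoi.levels)
            )


class TestGlszm:
    def test_single_zone_closed_forms(self):
        labels = np.zeros((3, 3, 3), dtype=np.int16)
        labels[0:2, 0:2, 0] = 1
        m = ft.build_glszm(ft.DiscretizedVoi(labels=labels, levels=8))
        assert ft.glszm_lgze(m) == 1.0 and ft.glszm_hgze(m) == 1.0
        labels8 = np.where(labels > 0, 8, 0).astype(np.int16)
        m8 = ft.build_glszm(ft.DiscretizedVoi(labels=labels8, levels=8))
        assert ft.glszm_lgze(m8) == pytest.approx(1 / 64)
        assert ft.glszm_hgze(m8) == pytest.approx(64.0)

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            dvoi = random_dvoi(rng)
            np.testing.assert_array_equal(
                ft.build_glszm(dvoi), glszm_bruteforce(dvoi.labels, dvoi.levels)
            )


class TestFeatureProperties:
    def test_ranges_on_random_vois(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            dvoi = random_dvoi(rng, shape=(5, 5, 5), levels=64)
            glcm = ft.build_glcm(dvoi)
            glrlm = ft.build_glrlm(dvoi)
            glszm = ft.build_glszm(dvoi)
            assert 0 < ft.glcm_homogeneity(glcm) <= 1
            assert 0 <= ft.glcm_entropy(glcm) <= 12
            assert 0 < ft.glrlm_sre(glrlm) <= 1
            assert ft.glrlm_lre(glrlm) >= 1
            assert 0 < ft.glszm_lgze(glszm) <= 1
            assert ft.glszm_hgze(glszm) >= 1

    def test_noise_raises_entropy_and_lowers_homogeneity(self):
        rng = np.random.default_rng(23)
        shape = (8, 8, 8)
        mask = mask_all(shape)
        entropies, homogeneities = [], []
        for sd in (0.0, 0.5, 1.5, 3.0):
            grid = np.clip(10.0 + rng.normal(0, sd, size=shape), 0, None)
            tex = ft.texture_features(suv_from_array(grid), mask)
            entropies.append(tex["entropy"])
            homogeneities.append(tex["homogeneity"])
        assert all(a < b for a, b in zip(entropies, entropies[1:]))
        assert all(a > b for a, b in zip(homogeneities, homogeneities[1:]))

    def test_small_voi_yields_nan_textures_with_warning(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[0, 0, :3] = True
        with pytest.warns(UserWarning, match="texture"):
            tex = ft.texture_features(suv_from_array(np.full((4, 4, 4), 5.0)), mask_from(m))
        assert all(np.isnan(v) for v in tex.values())


class TestAggregation:
    def _fv(self, mtv, mean, smax=10.0, scanner="DST"):
        return ft.FeatureVector(
            suv_max=smax,
            suv_mean=mean,
            suv_peak=smax * 0.9,
            mtv_cm3=mtv,
            tlg=mean * mtv,
            homogeneity=0.5,
            entropy=3.0,
            sre=0.9,
            lre=1.5,
            lgze=0.1,
            hgze=50.0,
            scanner=scanner,
        )

    def test_single_lesion_unchanged(self):
        fv = self._fv(4.0, 6.0)
        assert ft.aggregate_multifocal([fv]) == fv

    def test_hand_computed_two_lesions(self):
        agg = ft.aggregate_multifocal([self._fv(2.0, 4.0, smax=12.0), self._fv(6.0, 6.0, smax=8.0)])
        assert agg.mtv_cm3 == pytest.approx(8.0)
        assert agg.suv_mean == pytest.approx(5.5)
        assert agg.tlg == pytest.approx(44.0)
        assert agg.suv_max == 12.0  # index lesion's

    def test_identity_preserved_on_random_lesion_sets(self, rng):
        for _ in range(20):
            lesions = [
                self._fv(rng.uniform(0.5, 30), rng.uniform(2.5, 12), smax=rng.uniform(3, 25))
                for _ in range(rng.integers(1, 5))
            ]
            agg = ft.aggregate_multifocal(lesions)
            assert agg.tlg == pytest.approx(agg.suv_mean * agg.mtv_cm3, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ft.aggregate_multifocal([])


class TestExtraction:
    def test_tlg_identity_and_schema(self):
        rng = np.random.default_rng(29)
        grid = np.zeros((16, 10, 10))
        grid[2:7, 2:7, 2:7] = rng.uniform(4, 12, size=(5, 5, 5))
        grid[10:14, 2:6, 2:6] = rng.uniform(3, 8, size=(4, 4, 4))
        suv = suv_from_array(grid, spacing=(3, 3, 3), scanner="D690")
        fv = ft.extract_features(suv)
        assert fv.tlg == pytest.approx(fv.suv_mean * fv.mtv_cm3, rel=1e-9)
        assert fv.scanner == "D690"
        assert set(fv.as_dict()) | {"patient_id"} == set(ft.FEATURE_COLUMNS)

    def test_no_lesion_raises(self):
        with pytest.raises(ValidationError):
            ft.extract_features(suv_from_array(np.full((5, 5, 5), 1.0)))
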