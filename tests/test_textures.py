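"""Texture-feature unit tests: frozen hand examples, brute-force oracle
equivalence on random volumes, and the structural invariants (probability
mass, symmetry, mask-exterior and affine-rescaling invariance)."""

import math

import numpy as np
import pytest

from deltarad.textures import (
    DIRECTIONS_3D,
    FEATURE_NAMES,
    FeatureConfig,
    InputError,
    VolumeROI,
    extract_features,
    extract_feature_table,
    first_order,
    glcm_build,
    glcm_features,
    glrlm_gln,
    nestd,
    ngtdm_features,
    quantize,
)

from _oracles import (
    naive_glcm,
    naive_glcm_features,
    naive_gln,
    naive_nestd_map,
    naive_ngtdm,
)
from conftest import random_volume


def line_volume(values):
    """1D toy embedded in 3D: levels along x, mask covering the line."""
    vals = np.asarray(values, dtype=float)
    intens = vals.reshape(-1, 1, 1)
    mask = np.ones_like(intens, dtype=bool)
    vol = VolumeROI(intens, mask)
    return vol


class TestQuantize:
    def test_constant_roi_maps_to_level_one(self):
        vol = VolumeROI(np.full((3, 3, 3), 5.0), np.ones((3, 3, 3), bool))
        q = quantize(vol, 8)
        assert set(q.levels[q.mask]) == {1}

    def test_equal_width_forcing(self):
        vol = line_volume([0, 1, 2, 3])
        q = quantize(vol, 4)
        assert list(q.levels[:, 0, 0]) == [1, 2, 3, 4]

    def test_uniform_data_gives_uniform_histogram(self, rng):
        n = 10_000
        vals = rng.uniform(0, 1, n)
        vol = VolumeROI(vals.reshape(n, 1, 1), np.ones((n, 1, 1), bool))
        q = quantize(vol, 32)
        counts = np.bincount(q.levels[q.mask] - 1, minlength=32)
        from scipy.stats import chisquare

        assert chisquare(counts).pvalue > 0.01

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            VolumeROI(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool))


class TestGLCM:
    def test_1d_toy_counts(self):
        # levels 1 1 2 2, single +x direction, distance 1
        vol = line_volume([1, 1, 2, 2])
        q = quantize(vol, 2)
        p = glcm_build(q, 1, directions=((1, 0, 0),))
        # symmetric pairs: (1,1)x2, (1,2)x2, (2,2)x2 out of 6
        assert p[0, 0] == pytest.approx(2 / 6)
        assert p[0, 1] == pytest.approx(2 / 6 / 2)
        assert p[1, 0] == p[0, 1]
        assert p[1, 1] == pytest.approx(2 / 6)

    def test_constant_roi_single_entry(self):
        vol = VolumeROI(np.full((4, 4, 4), 2.0), np.ones((4, 4, 4), bool))
        q = quantize(vol, 8)
        p = glcm_build(q)
        assert p[0, 0] == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0)

    def test_direction_negation_invariance(self, rng):
        vol = random_volume(rng)
        q = quantize(vol, 5)
        p_pos = glcm_build(q, directions=DIRECTIONS_3D)
        p_neg = glcm_build(
            q, directions=tuple(tuple(-o for o in d) for d in DIRECTIONS_3D)
        )
        np.testing.assert_allclose(p_pos, p_neg, atol=1e-15)

    def test_probability_mass_and_symmetry(self, rng):
        for _ in range(5):
            vol = random_volume(rng)
            p = glcm_build(quantize(vol, 6))
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(p, p.T, atol=1e-15)
            assert (p >= 0).all()

    def test_two_point_entropy(self):
        p = np.array([[0.5, 0.0], [0.0, 0.5]])
        f = glcm_features(p)
        assert f["entropy"] == pytest.approx(1.0)
        assert f["contrast"] == pytest.approx(0.0)

    def test_uniform_2x2_features(self):
        # frozen from the brute-force oracle: direct summation over 4 cells
        p = np.full((2, 2), 0.25)
        f = glcm_features(p)
        assert f["entropy"] == pytest.approx(2.0)
        assert f["contrast"] == pytest.approx(0.5)
        assert f["cluster_tendency"] == pytest.approx(0.5)
        assert f["inverse_variance"] == pytest.approx(0.5)

    def test_features_match_naive_oracle_on_random_glcms(self, rng):
        for _ in range(100):
            L = int(rng.integers(2, 8))
            m = rng.random((L, L))
            m = m + m.T
            m /= m.sum()
            got = glcm_features(m)
            want = naive_glcm_features(m)
            for k in want:
                assert got[k] == pytest.approx(want[k], rel=1e-12, abs=1e-12), k


class TestNGTDM:
    def test_constant_roi_capped_coarseness(self):
        vol = VolumeROI(np.full((4, 4, 4), 7.0), np.ones((4, 4, 4), bool))
        f = ngtdm_features(quantize(vol, 8))
        assert f["coarseness"] == pytest.approx(1e6)
        assert f["complexity"] == pytest.approx(0.0)

    def test_center_voxel_hand_case(self):
        intens = np.ones((3, 3, 3))
        intens[1, 1, 1] = 2.0
        vol = VolumeROI(intens, np.ones((3, 3, 3), bool))
        q = quantize(vol, 2)
        from deltarad.textures import ngtdm_build

        s, n, n_valid = ngtdm_build(q)
        assert s[1] == pytest.approx(1.0)  # |2 - mean(26 ones)| = 1
        assert n[1] == 1 and n_valid == 27

    def test_matches_naive_oracle(self, rng):
        for _ in range(30):
            vol = random_volume(rng, max_side=8)
            L = int(rng.integers(2, 6))
            q = quantize(vol, L)
            got = ngtdm_features(q)
            want_c, want_x = naive_ngtdm(q.levels, q.mask, L)
            assert got["coarseness"] == pytest.approx(want_c, rel=1e-12)
            assert got["complexity"] == pytest.approx(want_x, rel=1e-12, abs=1e-12)


class TestGLRLM:
    def test_single_run(self):
        vol = line_volume([1, 1, 1, 1])
        q = quantize(vol, 2)
        assert glrlm_gln(q, directions=((1, 0, 0),)) == pytest.approx(1.0)

    def test_two_runs_hand_case(self):
        vol = line_volume([1, 1, 2, 2, 2])
        q = quantize(vol, 2)
        # runs {(1,2),(2,3)} -> GLN = (1+1)/2
        assert glrlm_gln(q, directions=((1, 0, 0),)) == pytest.approx(1.0)

    def test_voxel_conservation_single_direction(self, rng):
        from deltarad.textures import glrlm_build

        vol = random_volume(rng)
        q = quantize(vol, 4)
        r = glrlm_build(q, directions=((1, 0, 0),))
        lengths = np.arange(1, r.shape[1] + 1)
        assert (r @ lengths).sum() == pytest.approx(q.mask.sum())

    def test_matches_naive_oracle(self, rng):
        for _ in range(20):
            vol = random_volume(rng, max_side=8)
            L = int(rng.integers(2, 6))
            q = quantize(vol, L)
            got = glrlm_gln(q)
            want = naive_gln(q.levels, q.mask, L, DIRECTIONS_3D)
            assert got == pytest.approx(want, rel=1e-12)


class TestFirstOrder:
    def test_symmetric_values(self):
        vol = line_volume([1, 2, 3])
        f = first_order(vol)
        assert f["mean"] == pytest.approx(2.0)
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_normal_sample_kurtosis_near_three(self, rng):
        x = rng.standard_normal(100_000)
        vol = VolumeROI(x.reshape(-1, 1, 1), np.ones((len(x), 1, 1), bool))
        assert first_order(vol)["kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_affine_invariance_of_shape_moments(self, rng):
        vol = random_volume(rng)
        f0 = first_order(vol)
        scaled = VolumeROI(3.5 * vol.intensities + 10.0, vol.mask)
        f1 = first_order(scaled)
        assert f1["skewness"] == pytest.approx(f0["skewness"], rel=1e-9)
        assert f1["kurtosis"] == pytest.approx(f0["kurtosis"], rel=1e-9)
        assert f1["mean"] == pytest.approx(3.5 * f0["mean"] + 10.0, rel=1e-9)

    def test_zero_variance_undefined(self):
        vol = VolumeROI(np.full((3, 3, 3), 1.0), np.ones((3, 3, 3), bool))
        f = first_order(vol)
        assert math.isnan(f["skewness"]) and math.isnan(f["kurtosis"])


class TestNESTD:
    def test_constant_roi_is_zero(self):
        vol = VolumeROI(np.full((4, 4, 4), 3.0), np.ones((4, 4, 4), bool))
        val, nmap = nestd(vol, 8, 1, return_map=True)
        assert val == 0.0
        assert np.all(nmap[vol.mask] == 0.0)

    def test_definition_arithmetic(self):
        # both levels equally represented, raw SD = range/2
        # -> E_norm = 1, S_norm = 0.5, NESTD = 0.5 at the central voxel
        intens = np.zeros((2, 3, 3))
        intens[0] = -1.0
        intens[1] = 1.0
        vol = VolumeROI(intens, np.ones((2, 3, 3), bool))
        _, nmap = nestd(vol, 2, 1, return_map=True)
        # neighborhoods are half -1 / half +1: entropy 1 bit / log2(2) = 1,
        # SD = 1 = range/2 -> S_norm = 0.5
        assert nmap[0, 1, 1] == pytest.approx(0.5)

    def test_matches_naive_sliding_window(self, rng):
        from deltarad.textures import quantize as q_

        for _ in range(10):
            vol = random_volume(rng, max_side=7)
            L = 4
            got_val, got_map = nestd(vol, L, 1, return_map=True)
            q = q_(vol, L)
            want = naive_nestd_map(vol.intensities, q.levels, q.mask, L, 1)
            np.testing.assert_allclose(
                got_map[vol.mask], want[vol.mask], rtol=1e-12, atol=1e-12
            )
            assert got_val == pytest.approx(np.nanmean(want[vol.mask]), rel=1e-12)


class TestPanel:
    def test_mask_exterior_invariance(self, rng):
        vol = random_volume(rng)
        f0 = extract_features(vol)
        edited = vol.intensities.copy()
        edited[~vol.mask] += rng.normal(0, 100, (~vol.mask).sum())
        f1 = extract_features(VolumeROI(edited, vol.mask))
        for k in FEATURE_NAMES:
            assert f1[k] == pytest.approx(f0[k], rel=1e-12), k

    def test_affine_invariance_of_quantized_features(self, rng):
        vol = random_volume(rng)
        f0 = extract_features(vol)
        f1 = extract_features(VolumeROI(2.0 * vol.intensities + 5.0, vol.mask))
        for k in FEATURE_NAMES:
            if k == "mean":
                assert f1[k] == pytest.approx(2.0 * f0[k] + 5.0, rel=1e-9)
            else:
                assert f1[k] == pytest.approx(f0[k], rel=1e-9), k

    def test_table_cardinality_and_purity(self, rng):
        vol = random_volume(rng)
        vols = {"A": {1: vol, 2: vol, 3: vol}, "B": {1: vol, 2: vol, 3: vol}}
        table = extract_feature_table(vols, FeatureConfig(n_levels=8))
        assert len(table) == 2 * 3 * 13
        piv = table.pivot_table(
            index=["patient_id", "fraction"], columns="feature", values="value"
        )
        assert (piv.nunique() == 1).all()  # identical input -> identical rows

    def test_missing_fraction_one_rejected(self, rng):
        vol = random_volume(rng)
        with pytest.raises(InputError, match="fraction-1"):
            extract_feature_table({"A": {2: vol}})


def test_glcm_matrix_matches_naive_oracle(rng):
    for _ in range(15):
        vol = random_volume(rng, max_side=7)
        L = int(rng.integers(2, 6))
        q = quantize(vol, L)
        got = glcm_build(q)
        want = naive_glcm(q.levels, q.mask, L, 1, DIRECTIONS_3D)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-15)
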