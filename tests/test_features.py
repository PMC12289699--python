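"""Quantization, texture matrices and the 57-feature catalogue.

Matrix counts are checked against exhaustive enumeration oracles on small
random regions; feature formulas against hand-computed values on a 4-voxel
region whose matrices are enumerated by hand.
"""

import numpy as np
import pytest

from cerebrad.features import (
    FEATURE_NAMES,
    INTENSITY_FEATURES,
    TEXTURE_FEATURES,
    EmptyRegionError,
    build_matrices,
    extract_region_features,
    intensity_features,
    quantize_region,
    texture_features,
)
from _oracles import oracle_glcm, oracle_glrlm, oracle_glszm, oracle_ngtdm


def region_of(values3d, n_levels=4):
    vol = np.asarray(values3d, dtype=float)
    lm = np.ones(vol.shape, dtype=int)
    return quantize_region(vol, lm, 1, n_levels=n_levels)


class TestQuantize:
    def test_one_value_per_bin(self):
        q = region_of(np.array([[[0.0, 1.0], [2.0, 3.0]]]).reshape(1, 2, 2), n_levels=4)
        assert sorted(q.quantized[q.mask]) == [1, 2, 3, 4]

    def test_constant_region_degenerate(self):
        q = region_of(np.full((2, 2, 1), 7.7))
        assert q.degenerate
        assert set(q.quantized[q.mask]) == {1}

    def test_max_tie_goes_to_top_level(self):
        vol = np.array([0.0, 0.49, 1.0, 1.0]).reshape(1, 1, 4)
        q = region_of(vol, n_levels=2)
        assert list(q.quantized[q.mask]) == [1, 1, 2, 2]

    def test_empty_region_error_names_region(self):
        vol = np.zeros((2, 2, 2))
        lm = np.ones((2, 2, 2), dtype=int)
        with pytest.raises(EmptyRegionError) as err:
            quantize_region(vol, lm, 9)
        assert err.value.region_id == 9

    def test_uniform_occupancy_monte_carlo(self, rng):
        # DERIVED: uniform values on [0,1] into 32 equal bins, 1e4 voxels ->
        # expected occupancy 312.5 per level; the tolerance is the Monte-Carlo
        # 4-sigma band of a binomial(1e4, 1/32) count.
        vals = rng.uniform(size=(25, 20, 20))
        q = region_of(vals, n_levels=32)
        counts = q.histogram()
        sigma = np.sqrt(1e4 * (1 / 32) * (31 / 32))
        assert np.all(np.abs(counts - 312.5) < 4 * sigma + 1)

    def test_affine_invariance_of_quantized_domain(self, rng):
        vals = rng.normal(size=(4, 4, 3))
        qa = region_of(vals, n_levels=8)
        qb = region_of(2.5 * vals - 17.0, n_levels=8)
        assert np.array_equal(qa.quantized, qb.quantized)


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("shape,n_levels", [((3, 3, 3), 3), ((2, 3, 4), 4), ((5, 2, 2), 2)])
def test_matrix_counts_equal_exhaustive_enumeration(seed, shape, n_levels):
    """All four matrix families match brute-force enumeration on <=27-voxel regions."""
    rng = np.random.default_rng(seed)
    vol = rng.integers(0, n_levels, size=shape).astype(float)
    lm = (rng.uniform(size=shape) < 0.8).astype(int)  # ragged region
    if lm.sum() == 0:
        lm[0, 0, 0] = 1
    q = quantize_region(vol, lm, 1, n_levels=n_levels)
    m = build_matrices(q)

    levels = np.where(q.mask, q.quantized, 0)
    ref_glcm = oracle_glcm(levels, q.mask, n_levels)
    assert np.array_equal(m.glcm, ref_glcm)

    ref_glrlm = oracle_glrlm(levels, q.mask, n_levels)
    got = m.glrlm[:, : ref_glrlm.shape[1]]
    assert np.array_equal(got, ref_glrlm)
    assert m.glrlm[:, ref_glrlm.shape[1]:].sum() == 0

    ref_glszm = oracle_glszm(levels, q.mask, n_levels)
    assert np.array_equal(m.glszm[:, : ref_glszm.shape[1]], ref_glszm)

    ref_n, ref_s = oracle_ngtdm(levels, q.mask, n_levels)
    assert np.array_equal(m.ngtdm_n, ref_n)
    assert np.allclose(m.ngtdm_s, ref_s)


class TestMatrixInvariants:
    def test_four_voxel_hand_enumeration(self):
        # 2x2x1 region, levels [[1,1],[2,2]]: hand-enumerated counts.
        vol = np.array([[1.0, 1.0], [2.0, 2.0]]).reshape(2, 2, 1)
        q = region_of(vol, n_levels=2)
        m = build_matrices(q)
        # adjacent same-level pairs: 2 (one per level); cross-level pairs: 4
        # (2 across rows + 2 diagonal); symmetric counting doubles everything
        assert np.array_equal(m.glcm, np.array([[2, 4], [4, 2]]))
        # per level: one length-2 run along the level row, 24 length-1 runs
        # (2 across + 2+2 diagonal in-plane + 9 out-of-plane x 2)
        assert np.array_equal(m.glrlm[:, :2], np.array([[24, 1], [24, 1]]))
        # totals: sum over runs of len*count = 13 directions x 4 voxels
        lens = np.arange(1, m.glrlm.shape[1] + 1)
        assert (m.glrlm * lens).sum() == 13 * 4
        # zones: one zone of two voxels per level
        assert m.glszm[0, 1] == 1 and m.glszm[1, 1] == 1 and m.glszm.sum() == 2

    def test_constant_region_matrices(self):
        q = region_of(np.full((3, 3, 2), 4.2))
        m = build_matrices(q)
        nz = np.nonzero(m.glcm)
        assert list(zip(*nz)) == [(0, 0)]  # single diagonal cell
        assert m.glszm[0, 17] == 1 and m.glszm.sum() == 1  # one 18-voxel zone

    def test_glszm_partitions_voxels(self, rng):
        vol = rng.normal(size=(6, 5, 4))
        lm = (rng.uniform(size=vol.shape) < 0.7).astype(int)
        lm[0, 0, 0] = 1
        q = quantize_region(vol, lm, 1, n_levels=8)
        m = build_matrices(q)
        sizes = np.arange(1, m.glszm.shape[1] + 1)
        assert (m.glszm * sizes).sum() == q.n_voxels

    def test_normalizations(self, rng):
        vol = rng.normal(size=(5, 5, 3))
        lm = np.ones(vol.shape, dtype=int)
        m = build_matrices(quantize_region(vol, lm, 1, n_levels=6))
        assert abs(m.glcm_normalized.sum() - 1.0) < 1e-12
        assert abs(m.ngtdm_p.sum() - 1.0) < 1e-12


class TestIntensityFeatures:
    def test_closed_forms(self):
        q = region_of(np.array([1.0, 2.0, 3.0, 4.0, 5.0]).reshape(1, 1, 5))
        vals, flags = intensity_features(q)
        assert vals["mean"] == 3 and vals["median"] == 3
        assert vals["range"] == 4 and vals["variance"] == 2  # population convention
        assert vals["energy"] == 55 and vals["max"] == 5 and vals["min"] == 1
        assert np.isclose(vals["root_mean_square"], np.sqrt(11))
        assert not any(flags.values())

    def test_constant_region_degenerate_limits(self):
        q = region_of(np.full((2, 3, 1), 7.0))
        vals, flags = intensity_features(q)
        assert vals["standard_deviation"] == 0.0
        assert vals["h_uniformity"] == 1.0
        assert vals["skewness"] == 0.0 and flags["skewness"]
        assert vals["kurtosis"] == 0.0 and flags["kurtosis"]

    def test_gaussian_moments_match_convention(self, rng):
        # DERIVED: pinned convention is population skewness and non-excess
        # kurtosis, so N(0,1) gives skewness ~ 0 and kurtosis ~ 3.
        q = region_of(rng.normal(size=(50, 50, 40)))
        vals, _ = intensity_features(q)
        n = 1e5
        assert abs(vals["skewness"]) < 4 * np.sqrt(6 / n)
        assert abs(vals["kurtosis"] - 3.0) < 4 * np.sqrt(24 / n)


class TestTextureFeatures:
    def test_four_voxel_hand_oracle(self):
        """All 39 values against direct summation over the enumerated matrices."""
        vol = np.array([[1.0, 1.0], [2.0, 2.0]]).reshape(2, 2, 1)
        q = region_of(vol, n_levels=2)
        m = build_matrices(q)
        vals, _ = texture_features(m)

        # --- GLCM oracle: counts [[2,4],[4,2]] -> p = [[1/6,1/3],[1/3,1/6]]
        p = np.array([[2, 4], [4, 2]]) / 12
        ii, jj = np.meshgrid([1.0, 2.0], [1.0, 2.0], indexing="ij")
        assert np.isclose(vals["glcm_energy"], (p**2).sum())
        assert np.isclose(vals["glcm_contrast"], ((ii - jj) ** 2 * p).sum())
        mu = (np.array([1.0, 2.0]) * p.sum(axis=1)).sum()
        var = (((np.array([1.0, 2.0]) - mu) ** 2) * p.sum(axis=1)).sum()
        assert np.isclose(vals["glcm_variance"], var)
        assert np.isclose(
            vals["glcm_correlation"], (((ii - mu) * (jj - mu) * p).sum()) / var
        )
        assert np.isclose(vals["glcm_homogeneity"], (p / (1 + abs(ii - jj))).sum())
        p_sum = {2: p[0, 0], 3: p[0, 1] + p[1, 0], 4: p[1, 1]}
        assert np.isclose(vals["glcm_sum_average"], sum(k * v for k, v in p_sum.items()))
        assert np.isclose(vals["glcm_entropy"], -(p * np.log2(p)).sum())
        assert np.isclose(vals["glcm_dissimilarity"], (abs(ii - jj) * p).sum())

        # --- GLRLM oracle: hand-enumerated runs over the 13 directions.
        # In-plane: axis "across levels": 4 runs of length 1 (2 per level);
        # axis "along levels": 1 run of length 2 per level; the two in-plane
        # diagonals: 4 runs of length 1 (2 per level). Out-of-plane directions
        # (10 of 13) each see 4 runs of length 1.
        r = np.zeros((2, 2))
        r[:, 0] = 2 + 2 + 40 / 2  # per level: len-1 runs
        r[:, 1] = 1  # per level: one len-2 run
        nr = r.sum()
        pr = r / nr
        jgrid = np.array([[1.0, 2.0], [1.0, 2.0]])
        igrid = np.array([[1.0, 1.0], [2.0, 2.0]])
        assert np.isclose(vals["glrlm_short_run_emphasis"], (pr / jgrid**2).sum())
        assert np.isclose(vals["glrlm_long_run_emphasis"], (pr * jgrid**2).sum())
        assert np.isclose(vals["glrlm_gray_level_nonuniformity"], (r.sum(axis=1) ** 2).sum() / nr)
        assert np.isclose(vals["glrlm_run_length_nonuniformity"], (r.sum(axis=0) ** 2).sum() / nr)
        assert np.isclose(vals["glrlm_run_percentage"], nr / 4)
        assert np.isclose(vals["glrlm_low_gray_level_run_emphasis"], (pr / igrid**2).sum())
        assert np.isclose(vals["glrlm_high_gray_level_run_emphasis"], (pr * igrid**2).sum())
        assert np.isclose(vals["glrlm_short_run_low_gray_level_emphasis"], (pr / (igrid**2 * jgrid**2)).sum())
        assert np.isclose(vals["glrlm_short_run_high_gray_level_emphasis"], (pr * igrid**2 / jgrid**2).sum())
        assert np.isclose(vals["glrlm_long_run_low_gray_level_emphasis"], (pr * jgrid**2 / igrid**2).sum())
        assert np.isclose(vals["glrlm_long_run_high_gray_level_emphasis"], (pr * igrid**2 * jgrid**2).sum())
        mu_i = (igrid * pr).sum()
        mu_j = (jgrid * pr).sum()
        assert np.isclose(vals["glrlm_gray_level_variance"], (pr * (igrid - mu_i) ** 2).sum())
        assert np.isclose(vals["glrlm_run_length_variance"], (pr * (jgrid - mu_j) ** 2).sum())

        # --- GLSZM oracle: one zone of size 2 per level.
        z = np.array([[0.0, 1.0], [0.0, 1.0]])
        pz = z / 2
        assert np.isclose(vals["glszm_small_zone_emphasis"], (pz / jgrid**2).sum())
        assert np.isclose(vals["glszm_large_zone_emphasis"], (pz * jgrid**2).sum())
        assert np.isclose(vals["glszm_zone_percentage"], 2 / 4)
        assert np.isclose(vals["glszm_gray_level_nonuniformity"], (z.sum(axis=1) ** 2).sum() / 2)
        assert np.isclose(vals["glszm_zone_size_nonuniformity"], (z.sum(axis=0) ** 2).sum() / 2)

        # --- NGTDM oracle: every voxel has 3 in-region neighbours.
        # level-1 voxels: neighbours {1, 2, 2} -> mean 5/3 -> |1 - 5/3| = 2/3
        # level-2 voxels: neighbours {2, 1, 1} -> mean 4/3 -> |2 - 4/3| = 2/3
        n_i = np.array([2, 2])
        s_i = np.array([4 / 3, 4 / 3])
        p_i = n_i / 4
        eps = 1e-6
        assert np.isclose(vals["ngtdm_coarseness"], 1 / (eps + (p_i * s_i).sum()), rtol=1e-5)
        # contrast: 1/(Ng(Ng-1)) * sum p_i p_j (i-j)^2 * (1/N) sum s_i
        assert np.isclose(
            vals["ngtdm_contrast"], (2 * 0.5 * 0.5 * 1.0) / (2 * 1) * (s_i.sum() / 4)
        )

    def test_constant_region_limits(self):
        q = region_of(np.full((3, 3, 2), 1.5))
        vals, flags = texture_features(build_matrices(q))
        assert vals["glcm_contrast"] == 0.0
        assert vals["glcm_dissimilarity"] == 0.0
        assert vals["glcm_energy"] == 1.0
        assert vals["glcm_correlation"] == 0.0 and flags["glcm_correlation"]

    def test_checkerboard_maximizes_glcm_contrast(self, rng):
        # DERIVED: brute force over symmetric 2x2 normalized GLCMs with equal
        # marginals shows contrast <= 1, attained when all mass is off-diagonal.
        best = 0.0
        for off in np.linspace(0, 0.5, 501):
            p = np.array([[0.5 - off, off], [off, 0.5 - off]])
            best = max(best, 2 * off)  # contrast = (i-j)^2 mass = 2*off
        # 3-D checkerboard: every distance-1 neighbour along an axis flips level
        idx = np.indices((4, 4, 4)).sum(axis=0) % 2
        vol = idx.astype(float)
        q = region_of(vol, n_levels=2)
        vals, _ = texture_features(build_matrices(q))
        # axis-aligned pairs all contribute (i-j)^2=1; diagonal pairs 0, so the
        # in-practice value is below the 2-level bound but must stay <= best
        assert vals["glcm_contrast"] <= best + 1e-12
        # restricting to one row gives the pure alternating case = the bound
        row = region_of(np.array([0.0, 1, 0, 1, 0, 1]).reshape(1, 1, 6), n_levels=2)
        rvals, _ = texture_features(build_matrices(row))
        assert np.isclose(rvals["glcm_contrast"], best)

    def test_single_voxel_region_all_degenerate_but_finite(self):
        q = region_of(np.array([[[3.0]]]))
        m = build_matrices(q)
        assert m.degenerate
        vals, flags = texture_features(m)
        assert all(np.isfinite(v) for v in vals.values())
        assert all(flags.values())


class TestExtractRegionFeatures:
    def test_catalogue_counts(self, tiny_subject, tiny_label_map):
        rfv = extract_region_features(tiny_subject.volumes["T1"], tiny_label_map, 1, "T1")
        assert len(rfv.values) == 57
        assert tuple(rfv.values) == FEATURE_NAMES
        assert len(INTENSITY_FEATURES) == 18 and len(TEXTURE_FEATURES) == 39

    def test_determinism(self, tiny_subject, tiny_label_map):
        a = extract_region_features(tiny_subject.volumes["T2"], tiny_label_map, 2, "T2")
        b = extract_region_features(tiny_subject.volumes["T2"], tiny_label_map, 2, "T2")
        assert a.values == b.values

    def test_small_region_fully_flagged(self):
        vol = np.arange(8.0).reshape(2, 2, 2)
        lm = np.zeros((2, 2, 2), dtype=int)
        lm[0, 0, :] = 1  # 2 voxels < min_voxels
        rfv = extract_region_features(vol, lm, 1, "T1")
        assert all(rfv.flags.values())
        assert all(np.isfinite(v) for v in rfv.values.values())

    def test_affine_rescale_leaves_quantized_features_unchanged(self, tiny_subject, tiny_label_map):
        vol = tiny_subject.volumes["T1"]
        a = extract_region_features(vol, tiny_label_map, 3, "T1")
        b = extract_region_features(3.0 * vol + 50.0, tiny_label_map, 3, "T1")
        quantized_domain = [n for n in FEATURE_NAMES
                            if n.startswith(("glcm", "glrlm", "glszm", "ngtdm", "h_"))]
        for name in quantized_domain:
            assert np.isclose(a.values[name], b.values[name]), name
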