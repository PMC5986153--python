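import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from retoct import features as feat
from retoct import phantom
from retoct.core import Boundary, BoundarySet, OCTVolume, RetoctError
from conftest import brute_force_curviness

VOX = (3.9, 11.6, 120.0)


def _flat_boundaries(width, rows_by_name, n_bscans=1):
    bs = BoundarySet()
    for b in range(n_bscans):
        for name, row in rows_by_name.items():
            bs.add(Boundary(name, np.full(width, float(row)), b))
    return bs


class TestLayerMeanIntensity:
    def test_constant_band(self):
        img = np.full((1, 40, 20), 100, dtype=np.uint8)
        vol = OCTVolume(img, VOX)
        bs = _flat_boundaries(20, {"IZ-RPE": 10, "RBC": 20})
        assert feat.layer_mean_intensity(vol, bs, "RPE") == 100.0

    def test_two_row_band(self):
        img = np.zeros((1, 40, 20), dtype=np.uint8)
        img[0, 10] = 80
        img[0, 11] = 120
        vol = OCTVolume(img, VOX)
        bs = _flat_boundaries(20, {"IZ-RPE": 10, "RBC": 12})
        assert feat.layer_mean_intensity(vol, bs, "RPE") == 100.0

    def test_phantom_rnfl_mean(self, clean_phantom):
        vol, gt = clean_phantom
        assert feat.layer_mean_intensity(vol, gt.boundaries, "RNFL") == 150.0

    def test_empty_band_rejected(self):
        img = np.zeros((1, 40, 20), dtype=np.uint8)
        vol = OCTVolume(img, VOX)
        bs = _flat_boundaries(20, {"IZ-RPE": 10, "RBC": 10})
        with pytest.raises(RetoctError, match="empty"):
            feat.layer_mean_intensity(vol, bs, "RPE")


class TestDetectHis:
    def test_no_pixel_above_threshold(self, clean_phantom):
        vol, gt = clean_phantom
        assert feat.detect_his(vol, gt.boundaries).count == 0

    def test_phantom_spots_recovered_exactly(self, dme_phantom):
        vol, gt = dme_phantom
        mask = feat.detect_his(vol, gt.boundaries)
        assert np.array_equal(mask.mask, gt.his_mask.mask)

    def test_bright_pixels_outside_band_ignored(self):
        spec = phantom.PhantomSpec(n_bscans=1, noise_sd=0.0)
        vol, gt = phantom.generate_phantom(spec)
        img = vol.intensities.copy()
        img[0, 52:56, 10:20] = 255  # inside RNFL band, not INL..ONL
        mask = feat.detect_his(OCTVolume(img, VOX), gt.boundaries)
        assert mask.count == 0


class TestDetectDrusen:
    def test_flat_profile_empty(self, clean_phantom):
        vol, gt = clean_phantom
        assert feat.detect_drusen(vol, gt.boundaries).count == 0

    def test_bump_volume_recovered(self, drusen_phantom):
        vol, gt = drusen_phantom
        mask = feat.detect_drusen(vol, gt.boundaries)
        assert mask.volume_mm3 == pytest.approx(gt.drusen_mask.volume_mm3,
                                                rel=0.15)

    def test_ratio_gate_rejects_isointense_interior(self):
        spec = phantom.PhantomSpec(
            n_bscans=1, noise_sd=0.0,
            drusen_bumps=(phantom.DrusenBump(0, 1, 60, 14, 14,
                                             interior_intensity=200),))
        vol, gt = phantom.generate_phantom(spec)
        assert gt.drusen_mask.count > 0
        assert feat.detect_drusen(vol, gt.boundaries).count == 0

    def test_degenerate_width_rejected(self):
        img = np.zeros((1, 40, 1), dtype=np.uint8)
        vol = OCTVolume(img, VOX)
        bs = _flat_boundaries(1, {"ONL-ELM": 10, "RBC": 30})
        with pytest.raises(RetoctError):
            feat.detect_drusen(vol, bs)


class TestMaskVolume:
    def test_empty(self):
        from retoct.core import PathologyMask
        m = PathologyMask("HIS", np.zeros((1, 4, 4), dtype=bool), VOX)
        assert feat.mask_volume(m) == 0.0

    def test_arithmetic(self):
        from retoct.core import PathologyMask
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.ravel()[:1000] = True
        m = PathologyMask("HIS", mask, VOX)
        assert feat.mask_volume(m) == pytest.approx(1000 * 5.4288e-6, rel=1e-12)

    def test_phantom_ground_truth_exact(self, drusen_phantom):
        _, gt = drusen_phantom
        assert feat.mask_volume(gt.drusen_mask) == gt.true_features.drusen_volume_mm3


def _brute_extrema(series):
    """Oracle: literal neighbourhood-scan extrema on the plateau-collapsed series."""
    comp = [(0, series[0])]
    for i in range(1, len(series)):
        if series[i] != comp[-1][1]:
            comp.append((i, series[i]))
    out = []
    for j, (idx, v) in enumerate(comp):
        left = comp[j - 1][1] if j > 0 else None
        right = comp[j + 1][1] if j < len(comp) - 1 else None
        if (left is None or v > left) and (right is None or v > right):
            out.append((idx, v, "max"))
        elif (left is None or v < left) and (right is None or v < right):
            out.append((idx, v, "min"))
    return out


class TestAlternatingExtrema:
    def test_single_spike(self):
        lmm = feat.alternating_extrema([0, 0, 10, 0, 0])
        assert [(e.index, e.value, e.kind) for e in lmm] == [
            (0, 0, "min"), (2, 10, "max"), (3, 0, "min")]

    def test_monotone_series_endpoints(self):
        lmm = feat.alternating_extrema([1, 2, 3, 4])
        assert [(e.index, e.kind) for e in lmm] == [(0, "min"), (3, "max")]

    def test_constant_series_empty(self):
        assert feat.alternating_extrema([5, 5, 5, 5]) == []

    def test_random_series_match_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            s = rng.integers(0, 12, size=int(rng.integers(3, 40))).tolist()
            got = [(e.index, e.value, e.kind)
                   for e in feat.alternating_extrema(s)]
            assert got == _brute_extrema(s)

    @given(st.lists(st.integers(0, 8), min_size=3, max_size=50))
    @settings(max_examples=150, deadline=None)
    def test_alternation_property(self, s):
        lmm = feat.alternating_extrema(s)
        kinds = [e.kind for e in lmm]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        idxs = [e.index for e in lmm]
        assert idxs == sorted(idxs) and len(set(idxs)) == len(idxs)


def _E(items):
    return [feat.Extremum(i, float(v), k) for i, v, k in items]


class TestPruneExtrema:
    def test_fixpoint_when_all_differences_large(self):
        lmm = _E([(0, 0, "min"), (3, 9, "max"), (6, 1, "min")])
        assert feat.prune_extrema(lmm, 5.0) == lmm

    def test_worked_four_extremum_case(self):
        lmm = _E([(0, 0, "min"), (2, 4, "max"), (4, 0, "min"), (6, 10, "max")])
        out = feat.prune_extrema(lmm, 5.0)
        assert [(e.value, e.kind) for e in out] == [(0.0, "min"), (10.0, "max")]

    def test_full_pruning(self):
        lmm = _E([(0, 0, "min"), (2, 3, "max")])
        assert feat.prune_extrema(lmm, 5.0) == []

    def test_non_alternating_rejected(self):
        with pytest.raises(RetoctError):
            feat.prune_extrema(_E([(0, 0, "min"), (2, 3, "min")]), 5.0)

    @given(st.lists(st.integers(0, 20), min_size=3, max_size=60),
           st.floats(0.5, 10.0))
    @settings(max_examples=150, deadline=None)
    def test_contract_properties(self, s, delta):
        lmm = feat.alternating_extrema(s)
        out = feat.prune_extrema(lmm, delta)
        assert len(out) % 2 == len(lmm) % 2  # pairs removed
        vals = [e.value for e in out]
        assert all(abs(a - b) >= delta for a, b in zip(vals, vals[1:]))
        kinds = [e.kind for e in out]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestCurviness:
    @staticmethod
    def _pair(nl):
        width = len(nl)
        rbc = Boundary("RBC", np.full(width, 100.0))
        given = Boundary("MZ-EZ", 100.0 - np.asarray(nl, dtype=float))
        return rbc, given

    def test_constant_nl_zero(self):
        assert feat.curviness(*self._pair([7.0] * 20)) == 0.0

    def test_affine_nl_zero(self):
        nl = 3.0 + 0.5 * np.arange(30)
        assert feat.curviness(*self._pair(nl)) == 0.0

    def test_single_spike_hand_trace(self):
        nl = [0, 0, 0, 0, 10, 0, 0, 0, 0]
        assert feat.curviness(*self._pair(nl)) == pytest.approx(80 / 9, abs=1e-9)

    def test_double_spike_hand_trace(self):
        nl = [0, 0, 10, 0, 0, 0, 10, 0, 0]
        assert feat.curviness(*self._pair(nl)) == pytest.approx(280 / 9, abs=1e-9)

    def test_length_mismatch_rejected(self):
        rbc = Boundary("RBC", np.zeros(5))
        giv = Boundary("MZ-EZ", np.zeros(6))
        with pytest.raises(RetoctError):
            feat.curviness(rbc, giv)

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(20, 201))
            nl = np.round(rng.normal(20, 6, n), 3)
            got = feat.curviness(*self._pair(nl))
            assert got == pytest.approx(brute_force_curviness(nl), abs=1e-9)

    def test_spike_scaling_never_decreases_c1(self):
        rng = np.random.default_rng(4)
        base = np.zeros(60)
        base[[10, 30, 50]] = 8.0
        prev = 0.0
        for factor in (1.0, 1.5, 2.0, 4.0):
            nl = base * factor
            x = np.arange(60.0)
            fitted = np.polyval(np.polyfit(x, nl, 1), x)
            df = np.abs(nl - fitted)
            c1 = df[df > 3.0].sum()
            assert c1 >= prev - 1e-12
            prev = c1

    def test_well_separated_spike_count(self):
        for k in (1, 2, 3, 4):
            nl = np.zeros(120)
            for i in range(k):
                nl[15 + 25 * i] = 10.0
            lmm = feat.prune_extrema(feat.alternating_extrema(nl), 5.0)
            c2 = sum(1 for e in lmm if e.kind == "max")
            assert c2 == k


class TestThickness:
    def test_flat_band_any_sigma(self):
        bs = _flat_boundaries(30, {"ILM-RNFL": 20, "RBC": 50}, n_bscans=3)
        for sigma in (0.0, 1.0, 2.0):
            tm = feat.thickness_profile(bs, "ILM-RNFL", "RBC", sigma, 3.9)
            assert np.allclose(tm.values_um, 117.0)

    def test_sigma_zero_identity(self):
        bs = BoundarySet()
        rng = np.random.default_rng(0)
        lower = 50 + rng.uniform(0, 5, 20)
        bs.add(Boundary("ILM-RNFL", np.full(20, 20.0), 0))
        bs.add(Boundary("RBC", lower, 0))
        tm = feat.thickness_profile(bs, "ILM-RNFL", "RBC", 0.0, 1.0)
        assert np.array_equal(tm.values_um, (lower - 20.0)[None, :])

    def test_matches_direct_convolution(self):
        bs = BoundarySet()
        for b in range(5):
            bs.add(Boundary("ILM-RNFL", np.full(16, 10.0), b))
            bs.add(Boundary("RBC", 40.0 + np.linspace(0, 8, 16) + b, b))
        tm = feat.thickness_profile(bs, "ILM-RNFL", "RBC", 2.0, 3.9)
        # oracle: separable correlation with an explicitly sampled kernel and
        # symmetric (reflect-about-edge) padding
        raw = (bs.positions_grid("RBC") - 10.0) * 3.9
        r = int(4.0 * 2.0 + 0.5)
        x = np.arange(-r, r + 1)
        k = np.exp(-0.5 * (x / 2.0) ** 2)
        k /= k.sum()
        padded = np.pad(raw, r, mode="symmetric")
        expected = np.zeros_like(raw)
        for i in range(raw.shape[0]):
            for j in range(raw.shape[1]):
                window = padded[i:i + 2 * r + 1, j:j + 2 * r + 1]
                expected[i, j] = k @ window @ k
        assert np.allclose(tm.values_um, expected, atol=1e-9)

    def test_crossing_clamped(self, caplog):
        bs = _flat_boundaries(10, {"ILM-RNFL": 30, "RBC": 20})
        tm = feat.thickness_profile(bs, "ILM-RNFL", "RBC", 0.0, 1.0)
        assert np.all(tm.values_um == 0.0)

    def test_stats_constant(self):
        tm = feat.ThicknessMap(np.full((3, 5), 42.0), 0.0)
        assert feat.thickness_stats(tm) == (42.0, 42.0)

    def test_stats_percentile_formula(self):
        tm = feat.ThicknessMap(np.arange(1.0, 11.0).reshape(2, 5), 0.0)
        mean, p70 = feat.thickness_stats(tm)
        assert mean == pytest.approx(5.5)
        assert p70 == pytest.approx(7.3)  # h = (n-1)*0.7 + 1 = 7.3 (1-based)

    def test_stats_bimodal_mean(self):
        vals = np.array([[0.0] * 50 + [100.0] * 50])
        assert feat.thickness_stats(feat.ThicknessMap(vals, 0.0))[0] == 50.0


class TestExtractFeatures:
    def test_normal_phantom_analytic(self, clean_phantom):
        vol, gt = clean_phantom
        fv = feat.extract_features(vol, gt.boundaries)
        assert fv.his_volume_mm3 == 0.0
        assert fv.drusen_volume_mm3 == 0.0
        assert fv.curviness_mzez == 0.0
        assert fv.curviness_oplonl == 0.0
        assert fv.retina_mean_um == pytest.approx(118 * 3.9)
        assert fv.complex_mean_um == pytest.approx(26 * 3.9)
        assert fv.rpe_mean_um == pytest.approx(10 * 3.9)

    def test_amd_archetype_sign_pattern(self):
        base = phantom.default_class_templates()["AMD"].base
        spec = phantom.PhantomSpec(**{**base.__dict__, "noise_sd": 0.0})
        vol, gt = phantom.generate_phantom(spec)
        fv = feat.extract_features(vol, gt.boundaries)
        assert fv.drusen_volume_mm3 > 0
        assert fv.curviness_mzez > 0
        assert fv.his_volume_mm3 == 0.0

    def test_deterministic(self, dme_phantom):
        vol, gt = dme_phantom
        f1 = feat.extract_features(vol, gt.boundaries)
        f2 = feat.extract_features(vol, gt.boundaries)
        assert f1.to_dict() == f2.to_dict()

    def test_error_names_feature(self):
        spec = phantom.PhantomSpec(n_bscans=1, noise_sd=0.0)
        vol, gt = phantom.generate_phantom(spec)
        partial = BoundarySet()
        for b in gt.boundaries:
            if b.name != "IPL-INL":  # upper bound of the HIS search band
                partial.add(b)
        with pytest.raises(RetoctError, match="his_volume"):
            feat.extract_features(vol, partial)
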