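import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmisopk import (
    ParametricMap,
    PhantomSpec,
    RegionMask,
    contrast_ratio,
    extract_tac,
    fit_tac,
    k3_map,
    ki_map,
    map_positive_fraction,
    patlak_fit,
    patlak_transform,
    simulate_dynamic_pet,
)
from fmisopk.errors import InvalidBackgroundError, InvalidSpecError


@pytest.fixture(scope="module")
def small_phantom(cp, schedule):
    """16^3 noiseless phantom: fast enough for per-voxel fitting tests."""
    spec = PhantomSpec(
        shape=(16, 16, 16),
        tumor_center=(10.0, 10.0, 8.0), tumor_radius=3.2,
        blood_center=(5.0, 5.0, 8.0), blood_radius=1.8,
        hypoxic_fraction=0.30, noise_sigma0=0.0, seed=1)
    return spec, simulate_dynamic_pet(spec, cp, schedule)


class TestKiMap:
    def test_homogeneous_region_maps_constant(self, cp, schedule, small_phantom):
        _, ph = small_phantom
        pmap = ki_map(ph.image4d, cp, ph.masks["core"], schedule)
        vals = pmap.masked_values(ph.masks["core"])
        assert vals.size and np.ptp(vals) <= 1e-9 * max(vals.max(), 1e-30)

    def test_zero_activity_voxels_are_zero_or_invalid(self, cp, schedule):
        img = np.zeros((6, 6, 6, 52))
        body = RegionMask(np.ones((6, 6, 6), bool))
        pmap = ki_map(img, cp, body, schedule)
        vals = pmap.masked_values()
        assert np.all(vals == 0.0)

    def test_voxel_values_agree_with_patlak_fit(self, cp, schedule, small_phantom):
        """The vectorized per-voxel regression equals the scalar Patlak path."""
        _, ph = small_phantom
        pmap = ki_map(ph.image4d, cp, ph.masks["tumor"], schedule)
        idx = tuple(np.argwhere(ph.masks["core"].mask)[0])
        tac = extract_tac(ph.image4d,
                          RegionMask(np.isin(np.arange(16**3).reshape(16, 16, 16),
                                             [np.ravel_multi_index(idx, (16, 16, 16))])),
                          schedule)
        scalar = patlak_fit(patlak_transform(tac, cp), 30.0)
        assert pmap.values[idx] == pytest.approx(max(scalar.Ki, 0.0), rel=1e-9)

    def test_tumor_median_matches_apparent_influx(self, cp, schedule, small_phantom):
        """Voxel Patlak on the weighted signal estimates w_a*Ki."""
        spec, ph = small_phantom
        pmap = ki_map(ph.image4d, cp, ph.masks["tumor"], schedule)
        med = float(np.median(pmap.masked_values(ph.masks["core"])))
        truth = float(np.nanmedian(ph.true_ki_apparent[ph.masks["core"].mask]))
        assert med == pytest.approx(truth, rel=0.10)


class TestK3Map:
    def test_hypoxic_core_and_normoxic_rim_separate(self, cp, schedule, small_phantom):
        spec, ph = small_phantom
        pmap = k3_map(ph.image4d, cp, ph.masks["tumor"], schedule)
        core = pmap.masked_values(ph.masks["core"])
        rim = pmap.masked_values(ph.masks["rim"])
        assert np.median(core) == pytest.approx(spec.core_params.k3, rel=0.15)
        assert np.median(rim) < 0.005

    def test_homogeneous_tumor_maps_uniform(self, cp, schedule):
        spec = PhantomSpec(
            shape=(16, 16, 16),
            tumor_center=(10.0, 10.0, 8.0), tumor_radius=3.2,
            blood_center=(5.0, 5.0, 8.0), blood_radius=1.8,
            hypoxic_fraction=1.0,     # whole tumor hypoxic -> homogeneous
            noise_sigma0=0.0, seed=2)
        ph = simulate_dynamic_pet(spec, cp, schedule)
        pmap = k3_map(ph.image4d, cp, ph.masks["tumor"], schedule)
        vals = pmap.masked_values(ph.masks["tumor"])
        assert np.std(vals) / np.mean(vals) < 0.05

    def test_voxelwise_median_agrees_with_roi_fit(self, cp, schedule):
        spec = PhantomSpec(
            shape=(16, 16, 16),
            tumor_center=(10.0, 10.0, 8.0), tumor_radius=3.2,
            blood_center=(5.0, 5.0, 8.0), blood_radius=1.8,
            hypoxic_fraction=1.0, noise_sigma0=0.0, seed=2)
        ph = simulate_dynamic_pet(spec, cp, schedule)
        pmap = k3_map(ph.image4d, cp, ph.masks["tumor"], schedule)
        roi_res = fit_tac(extract_tac(ph.image4d, ph.masks["tumor"], schedule), cp)
        med = float(np.median(pmap.masked_values(ph.masks["tumor"])))
        assert med == pytest.approx(roi_res.params.k3, rel=0.05)

    def test_zero_voxels_marked_invalid(self, cp, schedule):
        img = np.zeros((6, 6, 6, 52))
        tumor = np.zeros((6, 6, 6), bool)
        tumor[2:4, 2:4, 2:4] = True
        pmap = k3_map(img, cp, RegionMask(tumor), schedule)
        assert not pmap.valid.any()


class TestMapStatistics:
    def _pmap(self, values, valid=None):
        values = np.asarray(values, float)
        valid = np.ones(values.shape, bool) if valid is None else valid
        return ParametricMap(values, valid, "k3", "1/min")

    def test_positive_fraction_extremes(self):
        tumor = RegionMask(np.ones((4, 4, 4), bool))
        assert map_positive_fraction(self._pmap(np.ones((4, 4, 4))), tumor, 0.5) == 100.0
        assert map_positive_fraction(self._pmap(np.zeros((4, 4, 4))), tumor, 0.5) == 0.0

    def test_designed_hypoxic_fraction_recovered(self, cp, schedule, small_phantom):
        spec, ph = small_phantom
        pmap = k3_map(ph.image4d, cp, ph.masks["tumor"], schedule)
        level = 0.5 * (spec.rim_params.k3 + spec.core_params.k3)
        frac = map_positive_fraction(pmap, ph.masks["tumor"], level)
        design = 100.0 * ph.masks["core"].n_voxels / ph.masks["tumor"].n_voxels
        assert frac == pytest.approx(design, abs=3.0)

    @given(levels=st.tuples(st.floats(0.0, 1.0), st.floats(0.0, 1.0)))
    @settings(derandomize=True, max_examples=25)
    def test_positive_fraction_monotone_in_level(self, levels):
        rng = np.random.default_rng(8)
        pmap = self._pmap(rng.uniform(0, 1, (5, 5, 5)))
        tumor = RegionMask(np.ones((5, 5, 5), bool))
        lo, hi = sorted(levels)
        assert (map_positive_fraction(pmap, tumor, hi)
                <= map_positive_fraction(pmap, tumor, lo))

    def test_contrast_ratio_basics(self):
        vol = np.ones((4, 4, 4))
        t = np.zeros((4, 4, 4), bool); t[:2] = True
        b = ~t
        assert contrast_ratio(vol, RegionMask(t), RegionMask(b)) == pytest.approx(1.0)
        vol2 = np.where(t, 2.0, 1.0)
        assert contrast_ratio(vol2, RegionMask(t), RegionMask(b)) == pytest.approx(2.0)
        with pytest.raises(InvalidBackgroundError):
            contrast_ratio(np.zeros((4, 4, 4)), RegionMask(t), RegionMask(b))

    def test_empty_masks_rejected(self, cp, schedule):
        with pytest.raises(InvalidSpecError):
            ki_map(np.zeros((4, 4, 4, 52)), cp,
                   RegionMask(np.zeros((4, 4, 4), bool)), schedule)
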