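import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wmhgrade.pv_separation import (
    LesionComponent,
    SeparationParams,
    anisotropic_ball,
    build_pv_mask,
    classify_component,
    extract_components,
    separate,
    summarize_volumes,
)
from wmhgrade.volume_io import LabelVolume, MaskBundle, ValidationError

from .oracles import brute_force_pv_mask


def _vol(arr, spacing=(1.0, 1.0, 6.0)):
    return LabelVolume(np.asarray(arr, bool), spacing, int(np.argmax(spacing)))


class TestBuildPvMask:
    def test_single_voxel_isotropic_matches_integer_ball(self):
        """A 10 mm shell around one voxel is the integer ball minus its centre."""
        arr = np.zeros((25, 25, 25), bool)
        arr[12, 12, 12] = True
        pv = build_pv_mask(_vol(arr, (1, 1, 1)), SeparationParams())
        ball = sum(
            1
            for i in range(-10, 11)
            for j in range(-10, 11)
            for k in range(-10, 11)
            if i * i + j * j + k * k <= 100
        )
        assert pv.count() == ball - 1

    def test_thick_slices_limit_element_extent(self):
        se = anisotropic_ball((1.0, 1.0, 6.0), 10.0)
        assert se.shape[2] == 3  # |k * 6| <= 10 forces k in {-1, 0, 1}

    def test_full_grid_ventricle_gives_empty_shell(self):
        pv = build_pv_mask(_vol(np.ones((6, 6, 3), bool)), SeparationParams())
        assert pv.count() == 0

    def test_empty_ventricles_rejected(self):
        with pytest.raises(ValidationError):
            build_pv_mask(_vol(np.zeros((4, 4, 2), bool)), SeparationParams())

    def test_small_grid_warns_when_element_spans_everything(self):
        arr = np.zeros((5, 5, 2), bool)
        arr[2, 2, 0] = True
        with pytest.warns(UserWarning, match="whole grid"):
            build_pv_mask(_vol(arr, (1, 1, 6)), SeparationParams())

    def test_matches_brute_force_distance_oracle(self, rng):
        """Dilation by the ellipsoidal element equals thresholding the
        anisotropic distance transform, on random masks and spacings."""
        for _ in range(8):
            shape = tuple(rng.integers(8, 20, 3))
            spacing = (
                float(rng.uniform(0.4, 1.0)),
                float(rng.uniform(0.4, 1.0)),
                float(rng.uniform(5.0, 6.0)),
            )
            vent = rng.random(shape) < 0.03
            if not vent.any():
                vent[tuple(rng.integers(0, shape))] = True
            pv = build_pv_mask(_vol(vent, spacing), SeparationParams())
            oracle = brute_force_pv_mask(vent, spacing, 10.0)
            assert np.array_equal(pv.voxels, oracle)

    def test_doubling_slice_thickness_never_widens_element(self):
        for sz in (2.0, 3.0, 5.0):
            thin = anisotropic_ball((1.0, 1.0, sz), 10.0)
            thick = anisotropic_ball((1.0, 1.0, 2 * sz), 10.0)
            assert thick.shape[2] <= thin.shape[2]


class TestExtractComponents:
    def _wmh(self, coords, shape=(6, 6, 3)):
        arr = np.zeros(shape, bool)
        for c in coords:
            arr[c] = True
        return _vol(arr)

    def test_diagonal_pair_8_connectivity(self):
        comps = extract_components(self._wmh([(1, 1, 0), (2, 2, 0)]))
        assert len(comps) == 1 and comps[0].area_vox == 2

    def test_diagonal_pair_4_connectivity(self):
        comps = extract_components(
            self._wmh([(1, 1, 0), (2, 2, 0)]), SeparationParams(in_plane_connectivity=4)
        )
        assert len(comps) == 2

    def test_never_merged_across_slices(self):
        comps = extract_components(self._wmh([(1, 1, 0), (1, 1, 1)]))
        assert len(comps) == 2
        assert sorted(c.slice_index for c in comps) == [0, 1]

    def test_empty_mask(self):
        assert extract_components(self._wmh([])) == []


class TestClassifyComponent:
    def _setup(self, n_total, n_in):
        """Component of n_total voxels in one slice, n_in inside the PV mask."""
        shape = (n_total, 2, 1)
        pv = np.zeros(shape, bool)
        pv[:n_in, 0, 0] = True
        coords = np.array([(i, 0, 0) for i in range(n_total)])
        comp = LesionComponent(slice_index=0, voxels=coords, area_vox=n_total)
        return comp, _vol(pv, (1, 1, 6))

    @pytest.mark.parametrize(
        "n_total,n_in,expected",
        [
            (10, 7, "PVH"),  # 0.7 > 0.6 -> whole component periventricular
            (10, 6, "split"),  # exactly 60% is NOT more than 60%
            (10, 0, "DWMH"),
            (10, 10, "PVH"),
        ],
    )
    def test_sixty_percent_rule(self, n_total, n_in, expected):
        comp, pv = self._setup(n_total, n_in)
        labels = classify_component(comp, pv)
        assert comp.assigned == expected
        if expected == "PVH":
            assert labels.all()
        elif expected == "DWMH":
            assert not labels.any()
        else:
            assert labels.sum() == n_in and comp.in_pv_vox == n_in

    def test_split_follows_pv_membership_voxelwise(self):
        comp, pv = self._setup(10, 5)
        labels = classify_component(comp, pv)
        assert np.array_equal(labels, pv.voxels[tuple(comp.voxels.T)])


class TestSeparate:
    def _random_bundle(self, rng, shape=(16, 16, 4), spacing=(1, 1, 6)):
        brain = np.ones(shape, bool)
        vent = rng.random(shape) < 0.02
        if not vent.any():
            vent[tuple(s // 2 for s in shape)] = True
        wmh = rng.random(shape) < 0.08
        return MaskBundle(
            _vol(brain, spacing), _vol(vent, spacing), _vol(wmh, spacing), "r"
        )

    def test_partition_disjoint_and_exhaustive(self, rng):
        for _ in range(20):
            bundle = self._random_bundle(rng)
            res = separate(bundle)
            assert not (res.pvh_mask.voxels & res.dwmh_mask.voxels).any()
            assert np.array_equal(
                res.pvh_mask.voxels | res.dwmh_mask.voxels, bundle.wmh.voxels
            )
            assert not (res.pv_mask.voxels & bundle.ventricles.voxels).any()

    def test_phantom_truth_recovered(self, two_lesion_phantom):
        bundle, truth = two_lesion_phantom
        res = separate(bundle)
        for lesion in truth.lesions:
            idx = tuple(lesion.voxels.T)
            target = res.pvh_mask.voxels if lesion.intended_class == "PVH" else res.dwmh_mask.voxels
            assert target[idx].all()

    def test_empty_wmh(self, rng):
        bundle = self._random_bundle(rng)
        bundle = MaskBundle(
            bundle.brain, bundle.ventricles, _vol(np.zeros(bundle.wmh.shape, bool)), "e"
        )
        res = separate(bundle)
        assert res.pvh_mask.count() == 0 and res.dwmh_mask.count() == 0
        assert res.components == []

    def test_wmh_equal_to_pv_mask_is_all_pvh(self, rng):
        bundle = self._random_bundle(rng)
        pv = build_pv_mask(bundle.ventricles)
        bundle = MaskBundle(bundle.brain, bundle.ventricles, pv, "pv")
        res = separate(bundle)
        assert np.array_equal(res.pvh_mask.voxels, pv.voxels)
        assert res.dwmh_mask.count() == 0

    def test_lower_pv_fraction_never_shrinks_pvh(self, rng):
        bundle = self._random_bundle(rng, shape=(20, 20, 4))
        counts = [
            separate(bundle, SeparationParams(pv_fraction=f)).pvh_mask.count()
            for f in (0.9, 0.6, 0.3, 0.1)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_partition_property_random_masks(seed):
    """PVH/DWMH always partition the WMH mask, whatever the geometry."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(4, 12, 3))
    vent = rng.random(shape) < 0.05
    vent[tuple(rng.integers(0, shape))] = True
    wmh = rng.random(shape) < 0.2
    bundle = MaskBundle(
        _vol(np.ones(shape, bool)), _vol(vent), _vol(wmh), "h"
    )
    res = separate(bundle)
    assert not (res.pvh_mask.voxels & res.dwmh_mask.voxels).any()
    assert np.array_equal(res.pvh_mask.voxels | res.dwmh_mask.voxels, wmh)


class TestSummarizeVolumes:
    def test_arithmetic(self):
        shape = (100, 100, 140)
        brain = np.ones(shape, bool)
        wmh = np.zeros(shape, bool)
        wmh.flat[:1400] = True
        vent = np.zeros(shape, bool)
        vent[50, 50, 70] = True
        bundle = MaskBundle(
            _vol(brain, (1, 1, 1)), _vol(vent, (1, 1, 1)), _vol(wmh, (1, 1, 1)), "a"
        )
        res = separate(bundle)
        s = summarize_volumes(res, bundle)
        assert s.brain_ml == pytest.approx(1400.0)
        assert s.pvh_ml + s.dwmh_ml == pytest.approx(1.4)
        assert s.pvh_ratio + s.dwmh_ratio == pytest.approx(0.001)

    def test_conservation_on_random_bundles(self, rng):
        for _ in range(10):
            shape = tuple(rng.integers(6, 14, 3))
            vent = np.zeros(shape, bool)
            vent[tuple(rng.integers(0, shape))] = True
            wmh = rng.random(shape) < 0.15
            bundle = MaskBundle(
                _vol(np.ones(shape, bool)), _vol(vent), _vol(wmh), "c"
            )
            res = separate(bundle)
            s = summarize_volumes(res, bundle)
            total = bundle.wmh.count() * np.prod(bundle.wmh.spacing) / 1000.0
            assert s.pvh_ml + s.dwmh_ml == pytest.approx(total, rel=1e-12)
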