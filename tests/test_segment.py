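"""Hemisphere utilities and the three core/hypoperfusion algorithms.

Brute-force voxel classification written inline serves as the independent
oracle for every algorithm.
"""

import numpy as np
import pytest

from ctperf import (
    AlgorithmConfig,
    compute_relative_maps,
    identify_pathological_side,
    mask_volume_ml,
    segment_cercare_mirror,
    segment_cercare_threshold,
    segment_isp,
    split_hemispheres,
)
from ctperf.maps import PerfusionMaps, RelativeMaps
from conftest import random_maps

SPACING = (2.0, 2.0, 2.0)


def _ellipsoid_mask(shape):
    zz, yy, xx = np.indices(shape, dtype=float)
    center = [(s - 1) / 2 for s in shape]
    semi = [0.45 * s for s in shape]
    return sum(((g - c) / a) ** 2 for g, c, a in zip((zz, yy, xx), center, semi)) <= 1.0


def _make_maps(shape, cbf, tmax, mtt=None, cbv=None, mask=None):
    mask = _ellipsoid_mask(shape) if mask is None else mask
    cbf = np.where(mask, cbf, 0.0)
    tmax = np.where(mask, tmax, 0.0)
    mtt = np.where(mask, 4.0 if mtt is None else mtt, 0.0)
    cbv = cbf * mtt / 60.0 if cbv is None else np.where(mask, cbv, 0.0)
    return PerfusionMaps(cbf=cbf, cbv=cbv, mtt=mtt, ttp=np.zeros(shape),
                         tmax=tmax, brain_mask=mask, spacing=SPACING)


class TestSplitHemispheres:
    def test_symmetric_mask_splits_evenly(self):
        mask = _ellipsoid_mask((16, 16, 16))
        labels = split_hemispheres(mask)
        n_left = np.count_nonzero(labels.side_mask("left"))
        n_right = np.count_nonzero(labels.side_mask("right"))
        plane = mask.shape[-1] * mask.shape[0]  # one plane's worth
        assert abs(n_left - n_right) <= plane
        assert n_left + n_right == np.count_nonzero(mask)

    def test_midline_override(self):
        mask = np.ones((4, 4, 20), dtype=bool)
        labels = split_hemispheres(mask, midline=10)
        assert np.all(labels.labels[:, :, :10] == 1)  # strictly left of 10
        assert np.all(labels.labels[:, :, 11:] == 2)

    def test_reflection_never_self_maps(self):
        # even-extent bounding box: the midline is a half-integer plane
        mask = _ellipsoid_mask((10, 10, 16))
        labels = split_hemispheres(mask)
        left = labels.side_mask("left")
        reflected = labels.reflect_mask(left)
        assert not np.any(reflected & left)

    def test_reflection_is_involutive_on_symmetric_mask(self):
        mask = _ellipsoid_mask((10, 10, 16))
        labels = split_hemispheres(mask)
        left = labels.side_mask("left")
        assert np.array_equal(labels.reflect_mask(labels.reflect_mask(left)), left)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_hemispheres(np.zeros((4, 4, 4), dtype=bool))


class TestIdentifyPathologicalSide:
    def test_planted_lesion_side_found(self):
        shape = (10, 16, 16)
        tmax = np.zeros(shape)
        tmax[4:6, 6:9, 11:14] = 9.0  # right half (higher x)
        maps = _make_maps(shape, cbf=50.0, tmax=tmax)
        labels = split_hemispheres(maps.brain_mask)
        side, flags = identify_pathological_side(maps.tmax, labels)
        assert side == "right"
        assert flags == ()

    def test_no_lesion_flagged_left_by_tiebreak(self):
        shape = (8, 8, 8)
        maps = _make_maps(shape, cbf=50.0, tmax=0.0)
        labels = split_hemispheres(maps.brain_mask)
        side, flags = identify_pathological_side(maps.tmax, labels)
        assert side == "left"
        assert "no_lesion" in flags

    def test_equal_bilateral_lesions_break_left(self):
        mask = np.ones((4, 8, 8), dtype=bool)
        tmax = np.zeros((4, 8, 8))
        tmax[1, 3, 1] = 8.0
        tmax[1, 3, 6] = 8.0  # mirror voxel, same magnitude
        labels = split_hemispheres(mask)
        side, _ = identify_pathological_side(tmax, labels)
        assert side == "left"


class TestCercareThreshold:
    def test_no_lesion_gives_zero_volumes(self):
        maps = _make_maps((8, 8, 8), cbf=50.0, tmax=0.0)
        labels = split_hemispheres(maps.brain_mask)
        res = segment_cercare_threshold(maps, labels)
        assert res.hypo_ml == 0.0 and res.core_ml == 0.0

    def test_core_is_brute_force_subregion(self):
        # lesion with a low-CBF subregion: only that region falls below
        # 30% of the contralateral mean (0.3 * 50 = 15; 10 < 15 <= 40)
        shape = (16, 24, 24)
        mask = _ellipsoid_mask(shape)
        zz, yy, xx = np.indices(shape)
        lesion = mask & (xx >= 16)
        sub = lesion & (zz < 8)
        cbf = np.where(mask, 50.0, 0.0)
        cbf[lesion] = 40.0
        cbf[sub] = 10.0
        tmax = np.where(lesion, 9.0, 0.0)
        maps = _make_maps(shape, cbf=cbf, tmax=tmax, mask=mask)
        labels = split_hemispheres(mask)
        res = segment_cercare_threshold(maps, labels)
        assert res.side == "right"
        assert res.baseline_cbf == pytest.approx(50.0)
        # brute-force oracle
        expected_core = lesion & (cbf < 0.3 * 50.0)
        assert np.array_equal(res.core_mask, expected_core)
        assert np.array_equal(res.hypo_mask, lesion)
        assert res.core_ml == pytest.approx(mask_volume_ml(sub, SPACING))

    def test_lesion_at_forty_percent_has_no_core(self):
        shape = (12, 16, 16)
        mask = _ellipsoid_mask(shape)
        _, _, xx = np.indices(shape)
        lesion = mask & (xx >= 11)
        cbf = np.where(mask, 50.0, 0.0)
        cbf[lesion] = 0.4 * 50.0
        maps = _make_maps(shape, cbf=cbf, tmax=np.where(lesion, 8.0, 0.0), mask=mask)
        labels = split_hemispheres(mask)
        res = segment_cercare_threshold(maps, labels)
        assert res.hypo_ml > 0.0
        assert res.core_ml == 0.0


class TestCercareMirror:
    def _lesion_phantom(self, artifact=False):
        shape = (16, 24, 24)
        mask = _ellipsoid_mask(shape)
        zz, yy, xx = np.indices(shape)
        lesion = mask & (xx >= 16) & (xx <= 19) & (yy >= 8) & (yy <= 15)
        sub = lesion & (zz < 8)
        cbf = np.where(mask, 50.0, 0.0)
        cbf[lesion] = 40.0
        cbf[sub] = 10.0
        if artifact:
            # bright vessel-like voxels far from the mirror ROI
            art = mask & (xx <= 4)
            cbf[art] = 400.0
        tmax = np.where(lesion, 9.0, 0.0)
        maps = _make_maps(shape, cbf=cbf, tmax=tmax, mask=mask)
        return maps, split_hemispheres(mask), lesion, sub

    def test_constant_contralateral_field_matches_threshold_core(self):
        maps, labels, _, _ = self._lesion_phantom()
        thr = segment_cercare_threshold(maps, labels)
        mir = segment_cercare_mirror(maps, labels)
        assert np.array_equal(thr.core_mask, mir.core_mask)

    def test_artifact_inflates_threshold_mean_but_not_mirror_median(self):
        maps, labels, lesion, sub = self._lesion_phantom(artifact=True)
        thr = segment_cercare_threshold(maps, labels)
        mir = segment_cercare_mirror(maps, labels)
        assert mir.baseline_cbf == pytest.approx(50.0)
        assert thr.baseline_cbf > 50.0
        # the inflated mean raises the threshold method's CBF cutoff, so its
        # core can only grow relative to the mirror method's
        assert not np.any(mir.core_mask & ~thr.core_mask)
        assert thr.core_ml >= mir.core_ml
        # mirror core is the designed brute-force subregion
        assert np.array_equal(mir.core_mask, lesion & (maps.cbf < 0.3 * 50.0))

    def test_empty_lesion_gives_zero_result(self):
        maps = _make_maps((8, 8, 8), cbf=50.0, tmax=0.0)
        labels = split_hemispheres(maps.brain_mask)
        res = segment_cercare_mirror(maps, labels)
        assert res.hypo_ml == 0.0 and res.core_ml == 0.0

    def test_midline_lesion_uses_fallback_and_flags(self):
        # lesion hugging the midline whose mirror leaves the brain mask:
        # build a mask occupying only the right half plus a sliver
        shape = (8, 10, 12)
        zz, yy, xx = np.indices(shape)
        mask = (xx >= 6) | (xx <= 2)  # gap where the mirror ROI would land
        cbf = np.where(mask, 50.0, 0.0)
        tmax = np.zeros(shape)
        lesion = mask & (xx >= 6) & (xx <= 7)
        tmax[lesion] = 9.0
        maps = _make_maps(shape, cbf=cbf, tmax=tmax, mask=mask)
        labels = split_hemispheres(mask, midline=5.5)
        res = segment_cercare_mirror(maps, labels)
        assert "mirror_fallback" in res.flags
        assert res.baseline_cbf == pytest.approx(50.0)


class TestIsp:
    def _maps_with(self, rmtt_value, cbv_value):
        shape = (12, 16, 16)
        mask = _ellipsoid_mask(shape)
        _, _, xx = np.indices(shape)
        lesion = mask & (xx >= 11)
        mtt = np.where(mask, 4.0, 0.0)
        mtt[lesion] = 4.0 * rmtt_value
        cbv = np.where(mask, 3.0, 0.0)
        cbv[lesion] = cbv_value
        cbf = np.where(mtt > 0, 60.0 * cbv / np.where(mtt > 0, mtt, 1.0), 0.0)
        maps = PerfusionMaps(cbf=cbf, cbv=cbv, mtt=mtt, ttp=np.zeros(shape),
                             tmax=np.where(lesion, 8.0, 0.0),
                             brain_mask=mask, spacing=SPACING)
        labels = split_hemispheres(mask)
        rel = compute_relative_maps(maps, labels)
        return maps, rel, labels, lesion

    def test_symmetric_phantom_has_empty_compartments(self):
        maps, rel, labels, _ = self._maps_with(1.0, 3.0)
        res = segment_isp(maps, rel, labels)
        assert res.hypo_ml == 0.0 and res.core_ml == 0.0

    def test_low_cbv_lesion_is_core_conventionally_and_swaps_as_printed(self):
        maps, rel, labels, lesion = self._maps_with(2.0, 1.0)
        conv = segment_isp(maps, rel, labels, AlgorithmConfig(isp_dialect="conventional"))
        printed = segment_isp(maps, rel, labels, AlgorithmConfig(isp_dialect="as-printed"))
        # brute-force: the whole lesion has rMTT approx 2 > 1.5 and CBV 1 < 2
        expected = lesion & (rel.rmtt > 1.5)
        assert np.array_equal(conv.core_mask, expected)
        assert conv.hypo_ml == 0.0
        assert np.array_equal(printed.hypo_mask, expected)
        assert printed.core_ml == 0.0

    def test_high_cbv_lesion_is_hypoperfused_conventionally(self):
        maps, rel, labels, lesion = self._maps_with(2.0, 3.0)
        res = segment_isp(maps, rel, labels)
        expected = lesion & (rel.rmtt > 1.5)
        assert np.array_equal(res.hypo_mask, expected)
        assert res.core_ml == 0.0

    def test_dialects_partition_the_same_lesion(self):
        maps, rel, labels, _ = self._maps_with(2.0, 1.0)
        for dialect in ("conventional", "as-printed"):
            res = segment_isp(maps, rel, labels, AlgorithmConfig(isp_dialect=dialect))
            assert res.hypo_ml + res.core_ml == pytest.approx(res.union_ml)


class TestMaskVolume:
    @pytest.mark.parametrize("n,spacing,expected", [
        (1000, (1.0, 1.0, 1.0), 1.0),
        (0, (1.0, 1.0, 1.0), 0.0),
        (123, (2.0, 2.0, 5.0), 2.46),
    ])
    def test_volume_arithmetic(self, n, spacing, expected):
        mask = np.zeros(2000, dtype=bool)
        mask[:n] = True
        assert mask_volume_ml(mask, spacing) == pytest.approx(expected)

    def test_non_positive_spacing_rejected(self):
        with pytest.raises(ValueError):
            mask_volume_ml(np.ones(4, dtype=bool), (1.0, 0.0, 1.0))


class TestProperties:
    """Invariants on randomly generated, structurally valid maps."""

    @pytest.mark.parametrize("seed", range(20))
    def test_core_subset_of_hypoperfused(self, seed):
        rng = np.random.default_rng(seed)
        maps = random_maps(rng)
        labels = split_hemispheres(maps.brain_mask)
        for func in (segment_cercare_threshold, segment_cercare_mirror):
            res = func(maps, labels)
            assert not np.any(res.core_mask & ~res.hypo_mask)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotonicity_in_thresholds(self, seed):
        rng = np.random.default_rng(100 + seed)
        maps = random_maps(rng)
        labels = split_hemispheres(maps.brain_mask)
        loose = segment_cercare_threshold(maps, labels, AlgorithmConfig(tmax_threshold_s=6.0))
        tight = segment_cercare_threshold(maps, labels, AlgorithmConfig(tmax_threshold_s=8.0))
        assert tight.hypo_ml <= loose.hypo_ml
        small = segment_cercare_threshold(maps, labels, AlgorithmConfig(rcbf_fraction=0.2))
        large = segment_cercare_threshold(maps, labels, AlgorithmConfig(rcbf_fraction=0.5))
        assert small.core_ml <= large.core_ml

    @pytest.mark.parametrize("seed", range(10))
    def test_left_right_flip_swaps_side_and_preserves_volumes(self, seed):
        rng = np.random.default_rng(200 + seed)
        maps = random_maps(rng, shape=(12, 20, 20))
        flipped = PerfusionMaps(
            cbf=maps.cbf[..., ::-1], cbv=maps.cbv[..., ::-1], mtt=maps.mtt[..., ::-1],
            ttp=maps.ttp[..., ::-1], tmax=maps.tmax[..., ::-1],
            brain_mask=maps.brain_mask[..., ::-1], spacing=maps.spacing,
        )
        labels = split_hemispheres(maps.brain_mask)
        labels_f = split_hemispheres(flipped.brain_mask)
        tol = mask_volume_ml(np.ones((12, 20), dtype=bool), maps.spacing)  # one plane
        for func in (segment_cercare_threshold, segment_cercare_mirror):
            a = func(maps, labels)
            b = func(flipped, labels_f)
            if a.hypo_ml > 0:
                assert a.side != b.side
            assert abs(a.hypo_ml - b.hypo_ml) <= tol
            assert abs(a.core_ml - b.core_ml) <= tol

    @pytest.mark.parametrize("seed", range(10))
    def test_isp_dialect_partition_on_random_maps(self, seed):
        rng = np.random.default_rng(300 + seed)
        maps = random_maps(rng)
        labels = split_hemispheres(maps.brain_mask)
        rel = compute_relative_maps(maps, labels)
        volumes = {}
        for dialect in ("conventional", "as-printed"):
            res = segment_isp(maps, rel, labels, AlgorithmConfig(isp_dialect=dialect))
            assert res.hypo_ml + res.core_ml == pytest.approx(res.union_ml)
            volumes[dialect] = res.union_ml
        assert volumes["conventional"] == pytest.approx(volumes["as-printed"])
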