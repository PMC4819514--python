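"""Section metrics against painted-count and exhaustive-search oracles."""

import dataclasses

import numpy as np
import pytest

from tumorquant.errors import InvalidInputError, UndefinedResultError
from tumorquant.histology import (
    SectionImageSet,
    align_channels,
    compute_section_metrics,
    mean_vessel_distance,
    necrotic_fraction,
    perfused_vessel_fraction,
    positive_fraction,
    viable_mask,
)


def _image_set(shape=(32, 32), **overrides) -> SectionImageSet:
    channels = {
        name: np.full(shape, 10.0)
        for name in ("hoechst_perfusion", "cd31", "ef5", "ki67", "tunel", "counterstain")
    }
    fields = dict(
        channels=channels,
        pixel_size_um=1.0,
        tumor_mask=np.ones(shape, bool),
        necrosis_mask=np.zeros(shape, bool),
        artifact_mask=np.zeros(shape, bool),
    )
    fields.update(overrides)
    return SectionImageSet(**fields)


class TestViableMask:
    def test_no_exclusions_gives_tumor_mask(self):
        s = _image_set()
        assert np.array_equal(viable_mask(s), s.tumor_mask)

    def test_full_necrosis_rejected(self):
        s = _image_set(necrosis_mask=np.ones((32, 32), bool))
        with pytest.raises(InvalidInputError):
            viable_mask(s)

    def test_pixel_count_matches_inclusion_exclusion(self, rng):
        shape = (40, 40)
        tumor = rng.random(shape) < 0.8
        necrosis = tumor & (rng.random(shape) < 0.3)
        artifact = rng.random(shape) < 0.1
        s = _image_set(shape, tumor_mask=tumor, necrosis_mask=necrosis, artifact_mask=artifact)
        expected = tumor.sum() - (tumor & necrosis).sum() - (tumor & ~necrosis & artifact).sum()
        assert viable_mask(s).sum() == expected


class TestPositiveFraction:
    def test_painted_fraction_recovered_exactly(self, rng):
        viable = np.ones((50, 50), bool)
        chan = np.full((50, 50), 10.0)
        pos = rng.choice(2500, size=750, replace=False)  # 30 %
        chan.ravel()[pos] = 200.0
        assert positive_fraction(chan, viable, threshold=100.0) == pytest.approx(30.0)

    def test_all_zero_channel_is_zero_percent(self):
        assert positive_fraction(np.zeros((8, 8)), np.ones((8, 8), bool), 1.0) == 0.0

    def test_uniform_suprathreshold_channel_is_100_percent(self):
        assert positive_fraction(np.full((8, 8), 5.0), np.ones((8, 8), bool), 1.0) == 100.0

    def test_otsu_fallback_separates_bimodal_channel(self, rng):
        chan = np.full((50, 50), 10.0)
        pos = rng.choice(2500, size=500, replace=False)
        chan.ravel()[pos] = 200.0
        assert positive_fraction(chan, np.ones((50, 50), bool)) == pytest.approx(20.0)


class TestPerfusedVesselFraction:
    def test_hoechst_superset_gives_100(self):
        cd31 = np.zeros((10, 10), bool)
        cd31[2:4, 2:4] = True
        assert perfused_vessel_fraction(cd31, np.ones((10, 10), bool)) == 100.0

    def test_disjoint_masks_give_0(self):
        cd31 = np.zeros((10, 10), bool)
        cd31[0, 0] = True
        hoechst = np.zeros((10, 10), bool)
        hoechst[5, 5] = True
        assert perfused_vessel_fraction(cd31, hoechst) == 0.0

    def test_painted_40_of_100(self, rng):
        cd31 = np.zeros((20, 20), bool)
        idx = rng.choice(400, size=100, replace=False)
        cd31.ravel()[idx] = True
        hoechst = np.zeros((20, 20), bool)
        hoechst.ravel()[idx[:40]] = True
        assert perfused_vessel_fraction(cd31, hoechst) == pytest.approx(40.0)

    def test_zero_cd31_is_undefined_not_zero(self):
        with pytest.raises(UndefinedResultError):
            perfused_vessel_fraction(np.zeros((5, 5), bool), np.ones((5, 5), bool))


class TestMeanVesselDistance:
    def test_everything_vascular_gives_zero(self):
        m = np.ones((9, 9), bool)
        assert mean_vessel_distance(m, m, 1.0) == 0.0

    def test_single_center_vessel_matches_exhaustive_search(self):
        """21x21 viable square, one vessel pixel at the center: the EDT mean
        must equal the brute-force mean Euclidean distance to the center."""
        shape = (21, 21)
        cd31 = np.zeros(shape, bool)
        cd31[10, 10] = True
        viable = np.ones(shape, bool)
        yy, xx = np.mgrid[0:21, 0:21]
        brute = np.sqrt((yy - 10.0) ** 2 + (xx - 10.0) ** 2).mean()
        assert mean_vessel_distance(cd31, viable, 1.0) == pytest.approx(brute, abs=1e-12)

    def test_random_masks_match_exhaustive_search(self, rng):
        for _ in range(5):
            cd31 = rng.random((16, 16)) < 0.05
            if not cd31.any():
                cd31[0, 0] = True
            viable = rng.random((16, 16)) < 0.9
            viable |= cd31
            vessels = np.argwhere(cd31)
            pix = np.argwhere(viable)
            brute = np.sqrt(((pix[:, None, :] - vessels[None, :, :]) ** 2).sum(-1)).min(1).mean()
            assert mean_vessel_distance(cd31, viable, 1.0) == pytest.approx(brute, abs=1e-9)

    def test_pixel_size_scales_linearly(self):
        cd31 = np.zeros((15, 15), bool)
        cd31[7, 7] = True
        viable = np.ones((15, 15), bool)
        d1 = mean_vessel_distance(cd31, viable, 1.0)
        assert mean_vessel_distance(cd31, viable, 2.0) == pytest.approx(2.0 * d1)

    def test_adding_vessels_never_increases_distance(self, rng):
        viable = np.ones((20, 20), bool)
        cd31 = np.zeros((20, 20), bool)
        cd31[3, 3] = True
        prev = mean_vessel_distance(cd31, viable, 1.0)
        for _ in range(6):
            free = np.argwhere(~cd31)
            y, x = free[rng.integers(len(free))]
            cd31[y, x] = True
            cur = mean_vessel_distance(cd31, viable, 1.0)
            assert cur <= prev + 1e-12
            prev = cur

    def test_no_vessels_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            mean_vessel_distance(np.zeros((5, 5), bool), np.ones((5, 5), bool), 1.0)


class TestNecroticFraction:
    def test_trivial_endpoints_and_painted_quarter(self):
        tumor = np.ones((20, 20), bool)
        assert necrotic_fraction(np.zeros_like(tumor), tumor) == 0.0
        assert necrotic_fraction(tumor, tumor) == 100.0
        necro = np.zeros_like(tumor)
        necro.ravel()[:100] = True  # 100 of 400
        assert necrotic_fraction(necro, tumor) == pytest.approx(25.0)

    def test_empty_tumor_rejected(self):
        with pytest.raises(InvalidInputError):
            necrotic_fraction(np.zeros((5, 5), bool), np.zeros((5, 5), bool))


def _structured(shape, rng):
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(rng.normal(0, 1, shape), 2.0) * 100.0 + 50.0


class TestAlignChannels:
    def test_known_shift_recovered(self, rng):
        ref = _structured((64, 64), rng)
        moved = np.zeros_like(ref)
        moved[3:, :-2] = ref[:-3, 2:]  # content moved by (+3, -2)
        s = _image_set((64, 64))
        s.channels["counterstain"] = ref
        s.channels["ef5"] = moved
        aligned, shifts = align_channels(s, "counterstain", window=5)
        assert shifts["ef5"] == (-3, 2)
        inner = (slice(8, 56), slice(8, 56))
        assert np.allclose(aligned.channels["ef5"][inner], ref[inner])

    def test_identical_channels_zero_shift(self, rng):
        ref = _structured((48, 48), rng)
        s = _image_set((48, 48))
        s.channels["counterstain"] = ref
        s.channels["ki67"] = ref.copy()
        _, shifts = align_channels(s, "counterstain", window=4)
        assert shifts["ki67"] == (0, 0)

    def test_pure_noise_channel_warned_and_unshifted(self, rng):
        s = _image_set((64, 64))
        s.channels["counterstain"] = _structured((64, 64), rng)
        s.channels["tunel"] = rng.normal(0, 1, (64, 64))
        with pytest.warns(UserWarning, match="indistinct"):
            aligned, shifts = align_channels(s, "counterstain", window=4)
        assert shifts["tunel"] == (0, 0)
        assert np.array_equal(aligned.channels["tunel"], s.channels["tunel"])


class TestTranslationInvariance:
    def test_fractions_invariant_under_joint_translation(self, rng):
        from tumorquant.synthetic import SectionPhantomSpec, make_section_phantom

        spec = SectionPhantomSpec(image_shape=(80, 80), n_vessels=12, seed=5)
        s, _ = make_section_phantom(spec)
        thr = {k: 100.0 for k in ("ef5", "ki67", "tunel", "cd31", "hoechst_perfusion")}
        m0 = compute_section_metrics(s, thr)

        # shifts stay within the phantom's 4-pixel border margin: nothing wraps
        def roll(a):
            return np.roll(np.roll(a, 3, axis=0), -2, axis=1)

        s2 = dataclasses.replace(
            s,
            channels={k: roll(v) for k, v in s.channels.items()},
            tumor_mask=roll(s.tumor_mask),
            necrosis_mask=roll(s.necrosis_mask),
            artifact_mask=roll(s.artifact_mask),
        )
        m1 = compute_section_metrics(s2, thr)
        for f in ("ef5_fraction", "ki67_fraction", "tunel_fraction",
                  "perfused_vessel_fraction", "necrotic_fraction"):
            assert getattr(m0, f) == pytest.approx(getattr(m1, f))
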