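"""Extended-Kety forward model, concentration conversion, and voxel fitting."""

import numpy as np
import pytest
from tumorquant.acquisition import AcquisitionParams, AIFModel
from tumorquant.errors import InvalidInputError, UndefinedResultError
from tumorquant.pk_model import (
    ConcentrationSeries,
    DynamicSeries,
    PKParameterMap,
    fit_kety_voxelwise,
    kety_forward,
    median_ktrans_viable,
    signal_to_concentration,
)
from tumorquant import synthetic, t1_mapping
from _oracles import brute_force_convolution


class TestKetyForward:
    def test_no_delivery_terms_gives_zero(self, aif, acq):
        ct = kety_forward(0.0, 0.3, 0.0, aif, acq.frame_times())
        assert np.all(ct == 0.0)

    def test_pure_plasma_voxel_equals_aif(self, aif, acq):
        t = acq.frame_times()
        assert np.allclose(kety_forward(0.0, 0.3, 1.0, aif, t), aif.plasma_concentration(t))

    def test_zero_ve_with_positive_ktrans_rejected(self, aif, acq):
        with pytest.raises(InvalidInputError):
            kety_forward(0.1, 0.0, 0.05, aif, acq.frame_times())

    def test_precontrast_frames_carry_no_tracer(self, aif, acq):
        ct = kety_forward(0.25, 0.3, 0.05, aif, acq.frame_times())
        assert np.all(ct[: acq.n_pre] == 0.0)

    @pytest.mark.parametrize(
        "params", [(0.05, 0.1, 0.0), (0.25, 0.3, 0.05), (0.5, 0.5, 0.1), (0.1, 0.45, 0.02)]
    )
    def test_exact_convolution_matches_fine_grid_quadrature(self, aif, acq, params):
        t = acq.frame_times()
        exact = kety_forward(*params, aif, t)
        numeric = brute_force_convolution(*params, aif, t)
        assert np.max(np.abs(exact - numeric)) < 1e-4

    def test_confluent_limit_kep_equals_decay_rate(self, acq):
        """kep == m1 exercises the t*exp(-mt) limit of the convolution."""
        aif = AIFModel(onset_time=312.0)
        ve = 0.5
        ktrans = aif.m1 * ve  # kep exactly m1
        t = acq.frame_times()
        exact = kety_forward(ktrans, ve, 0.0, aif, t)
        numeric = brute_force_convolution(ktrans, ve, 0.0, aif, t)
        assert np.max(np.abs(exact - numeric)) < 1e-4
        assert np.all(np.isfinite(exact))

    def test_monotone_in_vp_and_in_ktrans_during_uptake(self, aif, acq):
        """C_t rises with v_p everywhere; with Ktrans it rises during early
        uptake (shortly after the bolus). At late times a higher Ktrans also
        means faster efflux (k_ep = Ktrans/v_e), so global monotonicity in
        Ktrans does not hold for this model and is not asserted."""
        t = acq.frame_times()
        base = kety_forward(0.2, 0.3, 0.03, aif, t)
        assert np.all(kety_forward(0.2, 0.3, 0.05, aif, t) >= base)
        early = slice(acq.n_pre, acq.n_pre + 5)
        assert np.all(kety_forward(0.3, 0.3, 0.03, aif, t)[early] >= base[early])


class TestSignalToConcentration:
    def test_forward_inverse_closure(self, noiseless_phantom):
        spec, ph = noiseless_phantom
        fa = t1_mapping.FlipAngleMap(kappa=ph.truth_kappa, fit_ok=ph.mask)
        t1map = t1_mapping.T1Map(t1=ph.truth_t1, m0=np.full(ph.mask.shape, spec.m0), fit_ok=np.ones(ph.mask.shape, bool))
        conc = signal_to_concentration(ph.dynamic, t1map, fa, ph.relaxivity_r1)
        truth_rim = kety_forward(spec.ktrans_rim, spec.ve, spec.vp, ph.aif, ph.dynamic.frame_times)
        rim_vox = tuple(np.argwhere(ph.truth_pk.ktrans == spec.ktrans_rim)[0])
        assert np.max(np.abs(conc.conc[rim_vox] - truth_rim)) < 1e-6

    def test_constant_signal_gives_zero_concentration(self, acq):
        shape = (2, 2, 2)
        signal = np.full(shape + (acq.n_frames,), 37.5)
        dyn = DynamicSeries(signal=signal, frame_times=acq.frame_times(), acq=acq)
        fa = t1_mapping.FlipAngleMap(kappa=np.ones(shape), fit_ok=np.ones(shape, bool))
        t1map = t1_mapping.T1Map(t1=np.full(shape, 1500.0), m0=np.ones(shape), fit_ok=np.ones(shape, bool))
        conc = signal_to_concentration(dyn, t1map, fa)
        assert np.allclose(conc.conc, 0.0, atol=1e-12)

    def test_concentration_inversely_linear_in_relaxivity(self, noiseless_phantom):
        spec, ph = noiseless_phantom
        fa = t1_mapping.FlipAngleMap(kappa=ph.truth_kappa, fit_ok=ph.mask)
        t1map = t1_mapping.T1Map(t1=ph.truth_t1, m0=np.full(ph.mask.shape, spec.m0), fit_ok=np.ones(ph.mask.shape, bool))
        c1 = signal_to_concentration(ph.dynamic, t1map, fa, relaxivity_r1=3.9)
        c2 = signal_to_concentration(ph.dynamic, t1map, fa, relaxivity_r1=7.8)
        sel = ph.mask
        assert np.allclose(c2.conc[sel], 0.5 * c1.conc[sel], atol=1e-10)

    def test_failed_t1_voxels_marked_invalid(self, noiseless_phantom):
        spec, ph = noiseless_phantom
        fa = t1_mapping.FlipAngleMap(kappa=ph.truth_kappa, fit_ok=ph.mask)
        ok = np.ones(ph.mask.shape, bool)
        ok[0, 0, 0] = False
        t1map = t1_mapping.T1Map(t1=ph.truth_t1, m0=np.full(ph.mask.shape, spec.m0), fit_ok=ok)
        conc = signal_to_concentration(ph.dynamic, t1map, fa)
        assert not conc.valid[0, 0, 0]


def _conc_series(curves: np.ndarray, times: np.ndarray) -> ConcentrationSeries:
    n = curves.shape[0]
    return ConcentrationSeries(
        conc=curves,
        frame_times=times,
        baseline_r1=np.full(n, 1 / 1.5),
        relaxivity_r1=3.9,
        valid=np.ones(n, bool),
    )


class TestKetyFit:
    def test_noiseless_voxel_recovery_within_1e3_relative(self, aif, acq):
        t = acq.frame_times()
        truth = (0.25, 0.3, 0.05)
        curves = np.tile(kety_forward(*truth, aif, t), (3, 1))
        pk = fit_kety_voxelwise(_conc_series(curves, t), aif, np.ones(3, bool), n_pre=acq.n_pre)
        assert pk.fit_ok.all()
        for est, tr in zip((pk.ktrans[0], pk.ve[0], pk.vp[0]), truth):
            assert abs(est - tr) / tr < 1e-3

    def test_all_zero_voxel_pinned_at_bound_and_flagged(self, aif, acq):
        t = acq.frame_times()
        curves = np.zeros((2, t.size))
        pk = fit_kety_voxelwise(_conc_series(curves, t), aif, np.ones(2, bool), n_pre=acq.n_pre)
        assert np.all(pk.ktrans <= 1e-6)  # pinned at the lower bound
        assert not pk.fit_ok.any()
        assert not pk.enhancing.any()

    def test_empty_mask_rejected(self, aif, acq):
        t = acq.frame_times()
        with pytest.raises(InvalidInputError):
            fit_kety_voxelwise(_conc_series(np.zeros((2, t.size)), t), aif, np.zeros(2, bool))

    def test_vp_identified_worse_than_ktrans_at_slow_sampling(self, aif, acq, rng):
        """At 15.6 s frames, v_p is the weakly identified parameter: its
        Monte-Carlo relative error dominates that of Ktrans."""
        t = acq.frame_times()
        n = 40
        kt = rng.uniform(0.05, 0.5, n)
        ve = rng.uniform(0.1, 0.5, n)
        vp = rng.uniform(0.02, 0.1, n)
        curves = np.stack([kety_forward(kt[i], ve[i], vp[i], aif, t) for i in range(n)])
        noise = curves.max(axis=1, keepdims=True) / 20.0
        curves_noisy = curves + rng.normal(0, 1, curves.shape) * noise
        pk = fit_kety_voxelwise(_conc_series(curves_noisy, t), aif, np.ones(n, bool), n_pre=acq.n_pre)
        err_kt = np.median(np.abs(pk.ktrans - kt) / kt)
        err_vp = np.median(np.abs(pk.vp - vp) / vp)
        assert err_vp >= err_kt


class TestMedianKtransViable:
    def _pk(self, ktrans, ok=None, enhancing=None):
        ktrans = np.asarray(ktrans, float)
        ones = np.ones_like(ktrans)
        ok = np.ones(ktrans.shape, bool) if ok is None else ok
        return PKParameterMap(
            ktrans=ktrans, ve=ones * 0.3, vp=ones * 0.02, rss=ones * 0.0,
            fit_ok=ok, enhancing=enhancing,
        )

    def test_uniform_map_returns_that_value(self):
        pk = self._pk(np.full(10, 0.2))
        assert median_ktrans_viable(pk, np.ones(10, bool)) == pytest.approx(0.2)

    def test_rim_majority_drives_median(self):
        """60 % of viable voxels at the rim value: the median is the rim value."""
        ktrans = np.array([0.3] * 6 + [0.1] * 4)
        assert median_ktrans_viable(self._pk(ktrans), np.ones(10, bool)) == pytest.approx(0.3)

    def test_flagged_voxels_do_not_contribute(self):
        ktrans = np.array([0.2, 0.2, 99.0, 99.0])
        ok = np.array([True, True, False, False])
        assert median_ktrans_viable(self._pk(ktrans, ok), np.ones(4, bool)) == pytest.approx(0.2)

    def test_no_viable_voxels_is_undefined(self):
        pk = self._pk(np.ones(4), ok=np.zeros(4, bool))
        with pytest.raises(UndefinedResultError):
            median_ktrans_viable(pk, np.ones(4, bool))
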