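"""Fitting: secondary closed-form fits and global concentration-series fits."""

import numpy as np
import pytest

from labelkin import synthetic as syn
from labelkin.estimation import (
    DegenerateFitError,
    FitSpec,
    fit_competition,
    fit_extinction,
    fit_gaussian_profile,
    fit_one_phase,
    fit_sigmoidal,
    global_fit,
    kapp_from_rate,
)
from labelkin.models import CompetitionParams, Model1Params, Model2Params, derive_kapp
from labelkin.observables import (
    BOUND_COMPETITION,
    BOUND_TWOSTEP,
    ObservableMap,
)
from labelkin.preprocess import average_all_replicates, extract_baseline
from labelkin.tracedata import SignalKind, Trace

from conftest import make_fitted_set


def trace_from(time, signal, **kw):
    return Trace(trace_id="t", time=np.asarray(time, float),
                 signal=np.asarray(signal, float), **kw)


class TestOnePhase:
    def test_noiseless_recovery(self):
        t = np.linspace(0.0, 600.0, 200)
        y = 20.0 + 200.0 * (1.0 - np.exp(-0.01 * t))
        fit = fit_one_phase(trace_from(t, y))
        assert fit.Y0 == pytest.approx(20.0, rel=1e-3)
        assert fit.Ymax == pytest.approx(220.0, rel=1e-3)
        assert fit.k == pytest.approx(0.01, rel=1e-3)

    def test_half_life_property(self):
        Y0, Ymax, k = 20.0, 220.0, 0.01
        t_half = np.log(2.0) / k
        y_at_half = Y0 + (Ymax - Y0) * (1 - np.exp(-k * t_half))
        assert y_at_half == pytest.approx((Y0 + Ymax) / 2.0)

    def test_flat_trace_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_one_phase(trace_from(np.arange(10.0), np.full(10, 3.0)))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_one_phase(trace_from([0.0, 1.0, 2.0], [1.0, 2.0, 3.0]))


class TestKappFromRate:
    def test_direct_evaluation(self):
        assert kapp_from_rate(0.01, 50e-9) == pytest.approx(2e5)

    def test_zero_rate(self):
        assert kapp_from_rate(0.0, 1e-9) == 0.0

    def test_homogeneity(self):
        assert kapp_from_rate(0.01, 100e-9) == pytest.approx(
            kapp_from_rate(0.01, 50e-9) / 2.0
        )

    def test_nonpositive_protein_rejected(self):
        with pytest.raises(ValueError):
            kapp_from_rate(0.01, 0.0)


class TestSigmoidal:
    @staticmethod
    def curve(t_min, Y0, Ymax, t_half, H):
        out = np.full_like(t_min, Y0)
        pos = t_min > 0
        out[pos] = Y0 + (Ymax - Y0) / (1 + (t_half / t_min[pos]) ** H)
        return out

    def test_midpoint_property(self):
        for H in (0.5, 1.0, 2.0, 4.0):
            y = self.curve(np.array([20.0]), 1.0, 5.0, 20.0, H)
            assert y[0] == pytest.approx(3.0)

    def test_hyperbolic_identity_at_H1(self):
        x = np.linspace(1.0, 90.0, 50)
        hill = self.curve(x, 1.0, 5.0, 20.0, 1.0)
        hyperbola = 1.0 + 4.0 * x / (20.0 + x)
        np.testing.assert_allclose(hill, hyperbola, rtol=1e-12)

    def test_noiseless_recovery_at_imaging_cadence(self):
        t_s = np.arange(0.0, 90.0 * 60.0 + 1, 30.0)  # every 30 s over 90 min
        y = self.curve(t_s / 60.0, 1.0, 5.0, 20.0, 2.0)
        fit = fit_sigmoidal(trace_from(t_s, y, kind=SignalKind.RATIO))
        assert fit.t_half == pytest.approx(20.0, rel=5e-3)
        assert fit.H == pytest.approx(2.0, rel=5e-3)
        # noiseless data: the asymptotic CI collapses onto the estimate
        assert fit.ci_thalf[0] - 1e-6 <= 20.0 <= fit.ci_thalf[1] + 1e-6

    def test_flat_trace_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_sigmoidal(trace_from(np.arange(10.0), np.full(10, 2.0)))


class TestGaussianProfile:
    def test_fwhm_constant(self):
        profile = syn.generate_profile(np.sqrt(2 * np.log(2)) * 100.0)
        fit = fit_gaussian_profile(profile)
        assert fit.fwhm / fit.omega == pytest.approx(1.1774100226, rel=1e-9)

    def test_fwhm_108nm_recovery(self):
        # synthetic filament profile at the STED pixel size (25 nm)
        profile = syn.generate_profile(108.0)
        fit = fit_gaussian_profile(profile)
        assert fit.fwhm == pytest.approx(108.0, abs=1.0)

    def test_noisy_recovery(self):
        tpl = syn.line_profile(seed=9, noise_sd=0.02)
        fit = fit_gaussian_profile(syn.generate_profile(108.0, tpl))
        assert fit.fwhm == pytest.approx(108.0, abs=10.0)

    def test_symmetric_profile_centered(self):
        profile = syn.generate_profile(120.0, center=50.0)
        fit = fit_gaussian_profile(profile)
        assert fit.xc == pytest.approx(50.0, abs=1e-6)

    def test_no_peak_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_gaussian_profile(trace_from(np.arange(20.0), np.full(20, 1.0)))


class TestExtinction:
    def test_unit_case(self):
        c = np.array([1.0, 2.0, 3.0])
        fit = fit_extinction(c, 0.3 * c, path_length=0.3)
        assert fit.epsilon == pytest.approx(1.0)

    def test_beer_lambert_roundtrip(self):
        concs, absorb = syn.generate_dilution(epsilon=100_000.0, path_length=0.3)
        fit = fit_extinction(concs, absorb, path_length=0.3)
        assert fit.epsilon == pytest.approx(100_000.0, rel=1e-9)
        assert fit.a == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_absorbance_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            fit = fit_extinction(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert fit.epsilon == 0.0

    def test_zero_variance_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_extinction(np.array([2.0, 2.0, 2.0]), np.array([0.1, 0.2, 0.3]))


class TestGlobalFitModel1:
    def test_noiseless_recovery(self, small_platereader, fp_map):
        truth = Model1Params(1.51e5)
        av, r_free = make_fitted_set(
            small_platereader.with_(noise_sd=0.0), truth, fp_map
        )
        fit = global_fit(av, FitSpec(scheme="model1", r_free=r_free), fp_map)
        assert fit.estimates["k_app"] == pytest.approx(1.51e5, rel=1e-3)
        assert fit.adjusted_S0 == pytest.approx(20e-9, rel=1e-3)
        assert fit.estimates["r_bound"] == pytest.approx(300.0, rel=1e-3)

    def test_substrate_misspecification_recovered(self, small_platereader, fp_map):
        # traces generated with S0 10% above nominal; the adjustable
        # concentration must absorb the quantification error
        truth = Model1Params(1.51e5)
        tpl = small_platereader.with_(noise_sd=0.0, substrate_conc=22e-9)
        ts = syn.generate(tpl, truth, fp_map)
        relabeled = [t.with_(substrate_conc=20e-9) for t in ts]
        av = average_all_replicates(type(ts)(relabeled, ts.design))
        r_free = extract_baseline(av)
        fit = global_fit(av, FitSpec(scheme="model1", r_free=r_free), fp_map)
        assert fit.adjusted_S0 == pytest.approx(22e-9, rel=1e-3)
        assert fit.estimates["k_app"] == pytest.approx(1.51e5, rel=1e-3)

    def test_refuses_unaveraged_replicates(self, small_platereader, fp_map):
        ts = syn.generate(
            small_platereader.with_(replicates=3), Model1Params(1e5), fp_map
        )
        with pytest.raises(ValueError, match="average_all_replicates"):
            global_fit(ts, FitSpec(scheme="model1", r_free=60.0), fp_map)

    def test_single_concentration_warns(self, fp_map):
        tpl = syn.platereader_std(
            seed=1, noise_sd=0.0, protein_ladder=(0.0, 100e-9),
            grid=np.arange(0.0, 3600.0, 300.0),
        )
        av, r_free = make_fitted_set(tpl, Model1Params(1e5), fp_map)
        with pytest.warns(UserWarning, match="under-identified"):
            global_fit(av, FitSpec(scheme="model1", r_free=r_free), fp_map)


SF_MAP = ObservableMap(0.05, 0.25, BOUND_TWOSTEP)
SF_SMALL = dict(
    protein_ladder=(0.0, 3.13e-6, 1.0e-6, 0.25e-6),
    grid=np.arange(0.0, 2.0001, 0.01),
    replicates=1,
)


class TestGlobalFitModel2:
    def test_noiseless_recovery(self):
        truth = Model2Params(k1=2.08e7, k_minus1=50.0, k2=50.0)
        tpl = syn.stoppedflow(seed=4, noise_sd=0.0, **SF_SMALL)
        av, r_free = make_fitted_set(tpl, truth, SF_MAP)
        fit = global_fit(
            av, FitSpec(scheme="model2", r_free=r_free, n_starts=3), SF_MAP
        )
        assert derive_kapp(fit.rate_params()) == pytest.approx(
            derive_kapp(truth), rel=1e-3
        )
        assert fit.estimates["k1"] == pytest.approx(2.08e7, rel=1e-3)

    def test_fixing_true_k2_does_not_hurt(self):
        truth = Model2Params(k1=2.08e7, k_minus1=50.0, k2=50.0)
        tpl = syn.stoppedflow(seed=6, noise_sd=0.0, **SF_SMALL)
        av, r_free = make_fitted_set(tpl, truth, SF_MAP)
        free = global_fit(
            av, FitSpec(scheme="model2", r_free=r_free, n_starts=3), SF_MAP
        )
        fixed = global_fit(
            av,
            FitSpec(scheme="model2", r_free=r_free, fixed={"k2": 50.0}, n_starts=3),
            SF_MAP,
        )
        err = lambda f: abs(derive_kapp(f.rate_params()) / derive_kapp(truth) - 1)
        assert err(fixed) <= err(free) + 1e-3
        assert err(fixed) < 1e-3


class TestCompetitionFit:
    def test_noiseless_recovery(self, ):
        truth = CompetitionParams(kS_app=3e6, kI_app=2.8e4)
        obs = ObservableMap(60.0, 300.0, BOUND_COMPETITION)
        tpl = syn.competition(seed=3, noise_sd=0.0, grid=np.arange(0.0, 3601.0, 60.0))
        av, r_free = make_fitted_set(tpl, truth, obs)
        fit = fit_competition(av, FitSpec(scheme="competition", r_free=r_free), obs)
        assert fit.estimates["kS_app"] == pytest.approx(3e6, rel=1e-2)
        assert fit.estimates["kI_app"] == pytest.approx(2.8e4, rel=1e-2)

    def test_zero_competitor_only_reduces_to_model1(self, fp_map):
        obs = ObservableMap(60.0, 300.0, BOUND_COMPETITION)
        tpl = syn.competition(
            seed=3, noise_sd=0.0, competitor_ladder=(0.0,),
            grid=np.arange(0.0, 3601.0, 60.0),
        )
        truth = CompetitionParams(kS_app=3e6, kI_app=2.8e4)
        av, r_free = make_fitted_set(tpl, truth, obs)
        fit = fit_competition(
            av, FitSpec(scheme="competition", r_free=r_free, fixed={"kS_app": 3e6}), obs
        )
        assert fit.estimates["kI_app"] == pytest.approx(2.8e4, rel=1e-3)

    def test_inert_competitor_leaves_reporter_unchanged(self):
        obs = ObservableMap(60.0, 300.0, BOUND_COMPETITION)
        truth = CompetitionParams(kS_app=0.0, kI_app=2.8e4)
        tpl = syn.competition(seed=3, noise_sd=0.0, grid=np.arange(0.0, 3601.0, 60.0))
        ts = syn.generate(tpl, truth, obs)
        reaction = [t for t in ts if t.protein_conc > 0]
        ref = reaction[0]
        for t in reaction[1:]:
            np.testing.assert_allclose(t.signal, ref.signal, rtol=1e-9)

    def test_under_identified_without_anchor(self):
        obs = ObservableMap(60.0, 300.0, BOUND_COMPETITION)
        tpl = syn.competition(seed=3, noise_sd=0.0, grid=np.arange(0.0, 3601.0, 300.0))
        truth = CompetitionParams(kS_app=3e6, kI_app=2.8e4)
        ts = syn.generate(tpl, truth, obs)
        # drop the zero-competitor anchor but keep the baseline trace
        no_anchor = ts.select(lambda t: t.protein_conc == 0 or t.competitor_conc > 0)
        av = average_all_replicates(no_anchor)
        r_free = extract_baseline(av)
        with pytest.raises(ValueError, match="under-identified"):
            fit_competition(av, FitSpec(scheme="competition", r_free=r_free), obs)
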