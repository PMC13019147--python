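import numpy as np
import pytest

from bnctmicro.mc import SpecificEnergyHistogram
from bnctmicro.survival import (
    LQParams,
    MomentApproximationError,
    RadiationField,
    SKIN_WEIGHTS,
    TUMOR_WEIGHTS,
    WeightFactors,
    iso_effective_dose,
    mix_single_event_densities,
    mixed_field_zbars,
    nucleus_dose,
    skin_normalize,
    survival_mc,
    survival_moment,
    weighted_dose,
)
from bnctmicro.tables import SMKInputs


def delta_hist(z, width_frac=1e-4):
    lo, hi = z * (1 - width_frac), z * (1 + width_frac)
    edges = np.array([z * 1e-3, lo, hi])
    counts = np.array([0.0, 1000.0])
    return SpecificEnergyHistogram(edges=edges, counts=counts, n_events=1000,
                                   m1=z, m2=z**2)


def smk_inputs(kappa_intra=0.8, kappa_extra=0.2, zstar=20.0, zn=0.5):
    comps = ("B", "N", "H", "gamma")
    return SMKInputs(kappa_intra=kappa_intra, kappa_extra=kappa_extra,
                     zbar_n_D={c: zn for c in comps},
                     zbar_d_D={c: zstar * 1.2 for c in comps},
                     zbar_d_star={c: zstar for c in comps},
                     zbar_n_F={c: zn for c in comps})


class TestNucleusDose:
    def test_kappa_scaling(self):
        field = RadiationField(D_B=10.0, D_N=1.0, D_H=2.0, D_gamma=3.0)
        doses = nucleus_dose(field, smk_inputs(0.8, 0.4))
        assert doses["B"] == pytest.approx(12.0)
        assert doses["N"] == 1.0 and doses["H"] == 2.0 and doses["gamma"] == 3.0

    def test_zero_boron(self):
        field = RadiationField(D_B=0.0, D_N=1.0, D_H=0.0, D_gamma=0.0)
        assert nucleus_dose(field, smk_inputs(5.0, 5.0))["B"] == 0.0


class TestMixedField:
    def test_single_component(self):
        field = RadiationField(D_B=0.0, D_N=0.0, D_H=0.0, D_gamma=4.0)
        smk = smk_inputs()
        zstar, zn = mixed_field_zbars(field, smk)
        assert zstar == pytest.approx(smk.zbar_d_star["gamma"])
        assert zn == pytest.approx(smk.zbar_n_D["gamma"])

    def test_equal_dose_mean(self):
        smk = SMKInputs(kappa_intra=1.0, kappa_extra=0.0,
                        zbar_n_D={"B": 1.0, "gamma": 3.0},
                        zbar_d_D={"B": 1.0, "gamma": 3.0},
                        zbar_d_star={"B": 1.0, "gamma": 3.0})
        field = RadiationField(D_B=5.0, D_N=0.0, D_H=0.0, D_gamma=5.0)
        zstar, zn = mixed_field_zbars(field, smk)
        assert zstar == pytest.approx(2.0)
        assert zn == pytest.approx(2.0)

    def test_zero_field_rejected(self):
        field = RadiationField(D_B=0.0, D_N=0.0, D_H=0.0, D_gamma=0.0)
        with pytest.raises(ValueError):
            mixed_field_zbars(field, smk_inputs())


class TestSurvivalMC:
    def test_zero_dose(self):
        assert survival_mc(0.0, 10.0, delta_hist(1.0), LQParams()) == (1.0, 0.0)

    def test_poisson_thinning_identity(self):
        # beta0 = 0, delta event density: E[S] = exp(-lam (1 - e^{-a z_F}))
        lq = LQParams(alpha0=0.3, beta0=0.0)
        z_f, d = 0.5, 4.0
        s, se = survival_mc(d, 0.0, delta_hist(z_f), lq, n_samples=60_000,
                            seed=42)
        lam = d / z_f
        expected = np.exp(-lam * (1.0 - np.exp(-lq.alpha0 * z_f)))
        assert abs(s - expected) < 3 * se + 1e-4

    def test_many_small_events_recovers_mk_closed_form(self):
        lq = LQParams()
        zstar, d = 20.0, 5.0
        s, se = survival_mc(d, zstar, delta_hist(0.01), lq, n_samples=20_000,
                            seed=7)
        a = lq.alpha0 + lq.beta0 * zstar
        expected = np.exp(-a * d - lq.beta0 * d**2)
        assert abs(s - expected) < 3 * se + 1e-4

    def test_reproducible_and_se_scaling(self):
        lq = LQParams()
        h = delta_hist(0.5)
        s1, se1 = survival_mc(3.0, 10.0, h, lq, n_samples=5000, seed=3)
        s2, _ = survival_mc(3.0, 10.0, h, lq, n_samples=5000, seed=3)
        assert s1 == s2
        _, se4 = survival_mc(3.0, 10.0, h, lq, n_samples=20000, seed=3)
        assert se4 == pytest.approx(se1 / 2.0, rel=0.3)


class TestSurvivalMoment:
    def test_zero_variance_is_mk_closed_form(self):
        lq = LQParams()
        for d in (1.0, 5.0, 10.0):
            a = lq.alpha0 + lq.beta0 * 30.0
            expected = np.exp(-a * d - lq.beta0 * d**2)
            assert survival_moment(d, 30.0, 0.0, lq) == pytest.approx(expected,
                                                                      rel=1e-12)

    def test_monotone_in_dose(self):
        lq = LQParams()
        s = [survival_moment(d, 10.0, 0.2, lq) for d in (0.5, 1, 2, 4, 8)]
        assert np.all(np.diff(s) < 0)

    def test_large_variance_flagged(self):
        lq = LQParams(alpha0=2.0, beta0=0.5)
        with pytest.raises(MomentApproximationError):
            survival_moment(10.0, 50.0, 100.0, lq)

    def test_agrees_with_mc_at_small_variance(self):
        lq = LQParams()
        for d, zstar, zn in [(2.0, 10.0, 0.05), (5.0, 20.0, 0.1),
                             (8.0, 30.0, 0.1)]:
            s_m = survival_moment(d, zstar, zn, lq)
            s_mc, se = survival_mc(d, zstar, delta_hist(zn), lq,
                                   n_samples=30_000, seed=11)
            assert abs(np.log(s_m) - np.log(s_mc)) < 0.05 * abs(np.log(s_mc))


class TestIsoEffectiveDose:
    def test_identity_cases(self):
        lq = LQParams()
        assert iso_effective_dose(1.0, lq) == 0.0
        x = lq.X
        s = np.exp(-(lq.alpha * x + lq.beta * x**2))
        assert iso_effective_dose(s, lq) == pytest.approx(x, rel=1e-12)

    def test_reference_value(self):
        lq = LQParams(alpha=0.0633, beta=0.00822, X=2.0)
        assert iso_effective_dose(np.exp(-1.0), lq) == pytest.approx(12.53,
                                                                     abs=0.02)

    def test_invalid_survival(self):
        with pytest.raises(ValueError):
            iso_effective_dose(0.0, LQParams())
        with pytest.raises(ValueError):
            iso_effective_dose(1.5, LQParams())

    def test_photon_self_consistency(self):
        # pure photon-like field delivered as one X-Gy fraction returns X
        d = 3.0
        lq = LQParams(alpha0=0.0633, beta0=0.00822, alpha=0.0633,
                      beta=0.00822, X=d)
        s = survival_moment(d, 0.0, 0.0, lq)
        assert iso_effective_dose(s, lq) == pytest.approx(d, rel=1e-12)


class TestWeightedDose:
    def test_paper_weights_sum(self):
        field = RadiationField(D_B=1.0, D_N=1.0, D_H=1.0, D_gamma=1.0)
        assert weighted_dose(field, TUMOR_WEIGHTS) == pytest.approx(11.3)

    def test_unit_weights(self):
        field = RadiationField(D_B=1.0, D_N=2.0, D_H=3.0, D_gamma=4.0)
        w = WeightFactors(1.0, 1.0, 1.0, 1.0)
        assert weighted_dose(field, w) == pytest.approx(10.0)

    def test_zero_field(self):
        field = RadiationField(0.0, 0.0, 0.0, 0.0)
        assert weighted_dose(field, TUMOR_WEIGHTS) == 0.0


class TestSkinNormalize:
    def make_curves(self, b_per_ppm, n, h, g):
        import pandas as pd

        return pd.DataFrame({
            "depth_cm": [0.0, 1.0],
            "dose_B_per_ppm": [b_per_ppm, b_per_ppm],
            "dose_N": [n, n], "dose_H": [h, h], "dose_gamma": [g, g],
        })

    def test_factor_linearity(self):
        # weighted skin dose 6 Gy-Eq, target 12 -> factor 2
        # with 22 ppm skin boron: 2.5*(b*22) + 2.5*n + 2.5*h + 1*g = 6
        curves = self.make_curves(0.04, 0.4, 0.4, 1.8)
        skin = 2.5 * (0.04 * 22.0) + 2.5 * 0.4 + 2.5 * 0.4 + 1.8
        factor = skin_normalize(curves, 20.0, 1.1, SKIN_WEIGHTS, 12.0)
        assert factor == pytest.approx(12.0 / skin, rel=1e-12)

    def test_already_normalized(self):
        curves = self.make_curves(0.05, 0.5, 0.5, 1.0)
        skin = 2.5 * (0.05 * 22.0) + 2.5 + 1.0
        factor = skin_normalize(curves, 20.0, 1.1, SKIN_WEIGHTS, skin)
        assert factor == pytest.approx(1.0)

    def test_zero_skin_dose_rejected(self):
        with pytest.raises(ValueError):
            skin_normalize(self.make_curves(0.0, 0.0, 0.0, 0.0))


class TestMixDensities:
    def test_rate_weighted_mixture(self):
        h1, h2 = delta_hist(1.0), delta_hist(1.0)
        mixed = mix_single_event_densities({"B": h1, "gamma": h2},
                                           {"B": 3.0, "gamma": 1.0})
        assert mixed.m1 == pytest.approx(1.0)
        mixed2 = mix_single_event_densities({"B": delta_hist(2.0)},
                                            {"B": 5.0, "gamma": 0.0})
        assert mixed2.m1 == pytest.approx(2.0)
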