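"""Staged least-squares estimation and the LQ Taylor correspondence."""

import warnings

import numpy as np
import pandas as pd
import pytest

from loopsurv import (
    HrfFit,
    LethalityFit,
    ModelParameters,
    RsfFit,
    SurvivalDataset,
    analytic_mean_survival,
    fit_hrf,
    fit_lethality,
    fit_rsf,
    lq_taylor_coefficients,
    predict_combined,
)
from loopsurv.reference import all_parameter_sets

DOSES = np.array([1.0, 2.0, 4.0, 8.0])


def make_dataset(doses, sf, cell_line="L", o2=20.0, label="none"):
    return SurvivalDataset(pd.DataFrame({
        "cell_line": cell_line, "o2_percent": o2, "impairment_label": label,
        "dose_Gy": doses, "surviving_fraction": sf,
    }))


def curve(params, doses=DOSES, hrf=1.0, rsf=1.0):
    return analytic_mean_survival(params.with_alpha(params.alpha_dsb / hrf),
                                  np.asarray(doses, float), rsf)


class TestLethalityFit:
    def test_noiseless_recovery(self):
        true = ModelParameters(k_idsb=4e-3, k_cdsb=0.15)
        est = LethalityFit().fit(DOSES, curve(true))
        assert est.k_idsb_ == pytest.approx(4e-3, rel=1e-4)
        assert est.k_cdsb_ == pytest.approx(0.15, rel=1e-4)
        assert est.fit_result_.converged

    def test_sklearn_contract(self):
        from sklearn.base import clone
        est = LethalityFit(n_starts=3, random_state=1)
        cloned = clone(est)
        assert cloned.get_params()["n_starts"] == 3
        true = ModelParameters(k_idsb=3e-3, k_cdsb=0.2)
        cloned.fit(DOSES.reshape(-1, 1), curve(true))
        pred = cloned.predict(DOSES.reshape(-1, 1))
        np.testing.assert_allclose(pred, curve(true), rtol=1e-6)

    def test_single_dose_point_rejected(self):
        true = ModelParameters(k_idsb=4e-3, k_cdsb=0.15)
        with pytest.raises(ValueError, match="distinct nonzero doses"):
            LethalityFit().fit([2.0], curve(true, [2.0]))

    def test_zero_survival_record_rejected(self):
        with pytest.raises(ValueError, match="offending record"):
            LethalityFit().fit(DOSES, [0.9, 0.5, 0.1, 0.0])

    def test_zero_dose_records_excluded(self):
        """A dose-0 point (SF = 1 by normalization) must not alter the fit."""
        true = ModelParameters(k_idsb=4e-3, k_cdsb=0.15)
        sf = curve(true)
        plain = LethalityFit().fit(DOSES, sf)
        padded = LethalityFit().fit(np.r_[0.0, DOSES], np.r_[1.0, sf])
        assert padded.k_idsb_ == pytest.approx(plain.k_idsb_, rel=1e-10)
        assert padded.fit_result_.n_points == plain.fit_result_.n_points

    def test_objective_invariant_under_record_order(self, rng):
        true = ModelParameters(k_idsb=4e-3, k_cdsb=0.15)
        sf = curve(true) * np.exp(rng.normal(0, 0.1, DOSES.size))
        sf = np.minimum(sf, 1.0)
        order = rng.permutation(DOSES.size)
        a = LethalityFit().fit(DOSES, sf).fit_result_
        b = LethalityFit().fit(DOSES[order], sf[order]).fit_result_
        assert a.objective_value == pytest.approx(b.objective_value, rel=1e-12)
        assert a.estimates["k_idsb"] == pytest.approx(b.estimates["k_idsb"], rel=1e-8)

    def test_noisy_recovery_low_bias(self):
        """Median relative bias of both lethalities stays below 5% under 5%
        log-normal noise (200 replicates, triplicate design)."""
        true = ModelParameters(k_idsb=4e-3, k_cdsb=0.15)
        sf_true = curve(true)
        rng = np.random.default_rng(2024)
        bias_i, bias_c = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(200):
                noisy = np.minimum(
                    np.tile(sf_true, 3) * np.exp(rng.normal(0, 0.05, 3 * 4)), 1.0
                )
                est = LethalityFit().fit(np.tile(DOSES, 3), noisy)
                bias_i.append(est.k_idsb_ / 4e-3 - 1)
                bias_c.append(est.k_cdsb_ / 0.15 - 1)
        assert abs(np.median(bias_i)) < 0.05
        assert abs(np.median(bias_c)) < 0.05


class TestHrfFit:
    def test_noiseless_recovery(self):
        true = ModelParameters(k_idsb=4.83e-3, k_cdsb=0.169)
        est = HrfFit(k_idsb=true.k_idsb, k_cdsb=true.k_cdsb)
        est.fit(DOSES, curve(true, hrf=1.6))
        assert est.hrf_ == pytest.approx(1.6, abs=1e-3)

    def test_no_oxygen_effect_pins_at_lower_bound(self):
        true = ModelParameters(k_idsb=4e-3, k_cdsb=0.15)
        est = HrfFit(k_idsb=4e-3, k_cdsb=0.15)
        with pytest.warns(UserWarning, match="pinned at a bound"):
            est.fit(DOSES, curve(true))  # normoxic data fed to the hypoxia fit
        assert est.hrf_ == pytest.approx(1.0, abs=1e-6)


class TestRsfFit:
    def test_noiseless_recovery_large_factor(self):
        """A mutant-scale radiosensitization factor is recovered exactly."""
        true = ModelParameters(k_idsb=4.38e-3, k_cdsb=0.233)
        est = RsfFit(k_idsb=true.k_idsb, k_cdsb=true.k_cdsb)
        est.fit(DOSES, curve(true, rsf=9.6))
        assert est.rsf_ == pytest.approx(9.6, abs=1e-2)

    def test_no_impairment_gives_unity(self):
        true = ModelParameters(k_idsb=4e-3, k_cdsb=0.15)
        est = RsfFit(k_idsb=4e-3, k_cdsb=0.15)
        with pytest.warns(UserWarning, match="pinned at a bound"):
            est.fit(DOSES, curve(true))
        assert est.rsf_ == pytest.approx(1.0, abs=1e-6)

    def test_recovery_preserves_drug_concentration_ordering(self):
        true = ModelParameters(k_idsb=3.88e-3, k_cdsb=0.255)
        recovered = []
        for rsf in (1.7, 2.5, 4.2):
            est = RsfFit(k_idsb=true.k_idsb, k_cdsb=true.k_cdsb)
            est.fit(DOSES, curve(true, rsf=rsf))
            recovered.append(est.rsf_)
        assert recovered == sorted(recovered)
        np.testing.assert_allclose(recovered, [1.7, 2.5, 4.2], rtol=1e-4)


class TestWrappers:
    def test_fit_lethality_from_dataset(self):
        true = ModelParameters(k_idsb=4e-3, k_cdsb=0.15)
        fr = fit_lethality(make_dataset(DOSES, curve(true)))
        assert fr.estimates["k_idsb"] == pytest.approx(4e-3, rel=1e-4)
        assert fr.std_errors["k_idsb"] >= 0 or np.isnan(fr.std_errors["k_idsb"])

    def test_fit_hrf_and_rsf_record_frozen_lethalities(self):
        true = ModelParameters(k_idsb=4e-3, k_cdsb=0.15)
        hyp = make_dataset(DOSES, curve(true, hrf=1.4), o2=1.0)
        fr = fit_hrf(hyp, true)
        assert fr.fixed == {"k_idsb": 4e-3, "k_cdsb": 0.15}
        assert fr.estimates["hrf"] == pytest.approx(1.4, abs=1e-3)
        imp = make_dataset(DOSES, curve(true, rsf=2.5), label="drug")
        fr = fit_rsf(imp, true)
        assert fr.estimates["rsf"] == pytest.approx(2.5, abs=1e-3)

    def test_k_cov_propagation_inflates_rsf_error(self):
        """Propagating the frozen-lethality covariance must enlarge the RSF
        standard error (k_idsb uncertainty trades against the RSF)."""
        true = ModelParameters(k_idsb=4e-3, k_cdsb=0.15)
        rng = np.random.default_rng(11)
        sf = np.minimum(np.tile(curve(true, rsf=3.0), 3)
                        * np.exp(rng.normal(0, 0.1, 12)), 1.0)
        data = make_dataset(np.tile(DOSES, 3), sf, label="drug")
        bare = fit_rsf(data, true)
        k_cov = np.diag([(0.3 * 4e-3) ** 2, (0.2 * 0.15) ** 2])
        propagated = fit_rsf(data, true, k_cov=k_cov)
        assert propagated.std_errors["rsf"] > bare.std_errors["rsf"]
        assert propagated.estimates["rsf"] == bare.estimates["rsf"]


class TestPredictCombined:
    def test_unmodified_prediction_is_baseline(self, a549_params):
        np.testing.assert_allclose(
            predict_combined(a549_params, 1.0, 1.0, DOSES), curve(a549_params),
            rtol=1e-12,
        )

    def test_self_consistency_with_generator_curve(self, a549_params):
        np.testing.assert_allclose(
            predict_combined(a549_params, 1.31, 4.21, DOSES),
            curve(a549_params, hrf=1.31, rsf=4.21),
            rtol=1e-12,
        )

    def test_combination_kills_more_than_hypoxia_alone(self, default_params):
        params = default_params.with_lethality(3.88e-3, 0.255)
        combined = predict_combined(params, 1.31, 4.21, [4.0])
        hypoxic = predict_combined(params, 1.31, 1.0, [4.0])
        assert combined[0] < hypoxic[0]

    def test_workflow_order_invariance(self):
        """Fitting HRF before RSF or after gives identical combined
        predictions: the factors touch disjoint model components."""
        true = ModelParameters(k_idsb=4e-3, k_cdsb=0.15)
        hyp = make_dataset(DOSES, curve(true, hrf=1.5), o2=1.0)
        imp = make_dataset(DOSES, curve(true, rsf=3.0), label="drug")
        hrf_first = (fit_hrf(hyp, true).estimates["hrf"],
                     fit_rsf(imp, true).estimates["rsf"])
        rsf_first = (fit_rsf(imp, true).estimates["rsf"],
                     fit_hrf(hyp, true).estimates["hrf"])
        pred_a = predict_combined(true, hrf_first[0], hrf_first[1], DOSES)
        pred_b = predict_combined(true, rsf_first[1], rsf_first[0], DOSES)
        np.testing.assert_array_equal(pred_a, pred_b)


class TestLqTaylor:
    def test_zero_lethality_gives_zero_coefficients(self, default_params):
        assert lq_taylor_coefficients(default_params) == (0.0, 0.0)

    def test_reference_alpha_value(self, a549_params):
        alpha, _ = lq_taylor_coefficients(
            a549_params.with_lethality(4.83e-3, a549_params.k_cdsb)
        )
        assert alpha == pytest.approx(4.83e-3 * 5e-3 * 6000.0, rel=1e-12)
        assert alpha == pytest.approx(0.145, abs=5e-4)

    @pytest.mark.parametrize("label,params,rsf", all_parameter_sets(),
                             ids=lambda v: v if isinstance(v, str) else "")
    def test_matches_numerical_derivatives(self, label, params, rsf):
        """alpha and beta agree with the low-dose derivatives of
        -ln(mean survival) to 1e-4 relative, across the reference panel."""
        alpha, beta = lq_taylor_coefficients(params, rsf)
        doses = np.linspace(1e-4, 2e-2, 9)
        neglog = -np.log(analytic_mean_survival(params, doses, rsf))
        coeffs = np.polynomial.polynomial.polyfit(doses, neglog, deg=[1, 2, 3])
        assert coeffs[1] == pytest.approx(alpha, rel=1e-4)
        assert coeffs[2] == pytest.approx(beta, rel=1e-4)

    def test_lq_curve_matches_model_at_low_dose(self):
        """The quadratic LQ approximation tracks the closed form within 1%
        for doses up to 0.5 Gy."""
        for label, params, rsf in all_parameter_sets():
            alpha, beta = lq_taylor_coefficients(params, rsf)
            doses = np.linspace(0.0, 0.5, 11)
            lq = np.exp(-alpha * doses - beta * doses**2)
            model = analytic_mean_survival(params, doses, rsf)
            np.testing.assert_allclose(lq, model, rtol=0.01, err_msg=label)

    def test_saturated_rsf_rejected(self, a549_params):
        with pytest.raises(ValueError, match="exceeds 1"):
            lq_taylor_coefficients(a549_params, rsf=1000.0)
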