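"""The simultaneous regression model, its diagnostics and cross-validation."""

import numpy as np
import pytest

from chelstab import (
    AbsentValueError,
    ExcludedMetalError,
    StabilityRecord,
    fit_linear_per_metal,
    fit_model,
    fit_quadratic_per_ligand,
    get_record,
    loo_cv,
    make_features,
    predict,
)
from chelstab.fixtures import LIGANDS, METALS, MODEL_METALS


def test_features_normalized_on_nickel(records, chi):
    row = make_features(get_record(records, "Ni", "glycine"), chi, "K1")
    assert row.x == 0.0
    assert row.yref == pytest.approx(chi[("Ni", "glycine", "mono")])
    mn = make_features(get_record(records, "Mn", "glycine"), chi, "K1")
    assert mn.x == pytest.approx(
        chi[("Mn", "glycine", "mono")] - chi[("Ni", "glycine", "mono")]
    )
    assert mn.x2 == pytest.approx(mn.x**2)


def test_b2_features_use_bis_reference_even_without_ni_data(records, chi):
    # Ni/valine has no measured constants, yet its bis index anchors valine
    row = make_features(get_record(records, "Mn", "valine"), chi, "B2")
    assert row.yref == pytest.approx(chi[("Ni", "valine", "bis")])
    assert row.yref == pytest.approx(6.89, abs=0.005)


def test_feature_errors(records, chi):
    with pytest.raises(ExcludedMetalError):
        make_features(get_record(records, "Cu", "glycine"), chi, "K1")
    with pytest.raises(AbsentValueError):
        make_features(get_record(records, "Fe", "alanine"), chi, "K1")


def test_fit_uses_expected_record_counts(records, chi):
    assert fit_model(records, chi, "K1").n == 12
    assert fit_model(records, chi, "B2").n == 14


def test_fitted_nickel_value_is_linear_in_reference(records, chi):
    fit = fit_model(records, chi, "K1")
    expected = fit.a3 * chi[("Ni", "glycine", "mono")] + fit.intercept
    assert predict(fit, "Ni", "glycine", chi) == pytest.approx(expected)
    assert predict(fit, "Ni", "glycine", chi) == pytest.approx(6.21, abs=0.05)


def test_predict_rejects_copper(records, chi):
    fit = fit_model(records, chi, "K1")
    with pytest.raises(ExcludedMetalError):
        predict(fit, "Cu", "glycine", chi)


def test_singular_design_raises(records, chi):
    flat = {k: 1.0 for k in chi}  # all indices identical -> rank-deficient
    with pytest.raises(np.linalg.LinAlgError):
        fit_model(records, flat, "K1")


def test_ols_idempotent_on_noiseless_data(records, chi):
    fit = fit_model(records, chi, "K1")
    synthetic = [
        StabilityRecord(r.metal, r.ligand, float(f), None)
        for r, f in zip(fit.records, fit.fitted)
    ]
    refit = fit_model(synthetic, chi, "K1")
    assert refit.coef == pytest.approx(fit.coef, abs=1e-8)
    assert refit.se_fit == pytest.approx(0.0, abs=1e-10)


def test_loo_residual_zero_when_point_on_others_model(records, chi):
    fit = fit_model(records, chi, "K1")
    # make every response exactly the model value: each held-out point
    # is then reproduced by the model fit on the rest
    synthetic = [
        StabilityRecord(r.metal, r.ligand, float(f), None)
        for r, f in zip(fit.records, fit.fitted)
    ]
    loo = loo_cv(synthetic, chi, "K1")
    assert np.allclose(loo.loo_residuals, 0.0, atol=1e-8)
    assert loo.se_cv == pytest.approx(0.0, abs=1e-8)


def test_loo_se_not_smaller_than_fit_se(records, chi):
    for resp in ("K1", "B2"):
        fit = fit_model(records, chi, resp)
        loo = loo_cv(records, chi, resp)
        assert loo.se_cv >= fit.se_fit


def test_parameter_recovery_from_synthetic_responses(records, chi):
    """Known coefficients + sigma=0.05 noise on the real design are recovered."""
    rng = np.random.default_rng(20260922)
    truth = np.array([12.0, -12.0, -0.7, 7.5])
    base = fit_model(records, chi, "K1")
    X = np.array([[f.x2, f.x, f.yref, 1.0] for f in base.features])
    y = X @ truth + rng.normal(0.0, 0.05, size=len(X))
    synthetic = [
        StabilityRecord(r.metal, r.ligand, float(v), None)
        for r, v in zip(base.records, y)
    ]
    fit = fit_model(synthetic, chi, "K1")
    assert np.all(np.abs(fit.coef - truth) <= 3 * fit.se_coef)


def test_per_metal_lines_slope_negative(records, chi):
    # Fe has a single log K1 point, so its line exists only for log beta2
    for metal in ("Mn", "Co", "Ni", "Cu"):
        slope, _, r = fit_linear_per_metal(records, chi, "K1", metal)
        assert slope < 0
        assert -1 <= r <= 1
    for metal in METALS:
        slope, _, _ = fit_linear_per_metal(records, chi, "B2", metal)
        assert slope < 0


def test_two_point_line_is_exact(records, chi):
    two = [r for r in records if r.metal == "Ni" and r.ligand in ("glycine", "alanine")]
    _, _, r = fit_linear_per_metal(two, chi, "K1", "Ni")
    assert abs(r) == pytest.approx(1.0)


def test_quadratic_per_ligand_near_interpolates(records, chi):
    coeffs, deviation = fit_quadratic_per_ligand(records, chi, "K1", "glycine")
    for metal in MODEL_METALS:
        rec = get_record(records, metal, "glycine")
        x = chi[(metal, "glycine", "mono")]
        assert np.polyval(coeffs, x) == pytest.approx(rec.logK1, abs=0.1)
    # Cu sits well above the trend of the other four metals
    assert deviation is not None and deviation > 0


def test_quadratic_through_three_points_is_exact(records, chi):
    three = [r for r in records
             if r.ligand == "alanine" and r.metal in ("Mn", "Co", "Ni")]
    coeffs, _ = fit_quadratic_per_ligand(three, chi, "K1", "alanine")
    for rec in three:
        x = chi[(rec.metal, "alanine", "mono")]
        assert np.polyval(coeffs, x) == pytest.approx(rec.logK1, abs=1e-8)
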