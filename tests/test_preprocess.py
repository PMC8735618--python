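"""Normalization, binning and feature-matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import small_config
from seropls import (
    DEFAULT_BINS,
    BinDefinition,
    FeatureMatrix,
    SpectrumSet,
    bin_spectra,
    integrate_features,
    normalize_spectra,
    scale_features,
    simulate_cohort,
    uniform_bins,
)
from seropls.preprocess import fit_scaler


def flat_spectra(n=2, lo=0.0, hi=6.0, step=0.01, value=1.0):
    ppm = np.arange(lo, hi + step / 2, step)
    return SpectrumSet(ppm, np.full((n, ppm.size), value), [f"s{i}" for i in range(n)])


# --- normalization ---------------------------------------------------------


def test_normalize_none_is_identity():
    s = flat_spectra()
    out = normalize_spectra(s, "none")
    assert np.array_equal(out.intensities, s.intensities)


def test_total_area_removes_dilution():
    ppm = np.arange(0.0, 6.0, 0.01)
    shape = np.exp(-0.5 * ((ppm - 1.3) / 0.1) ** 2) + 0.1
    s = SpectrumSet(ppm, np.vstack([shape, 2.0 * shape]), ["a", "b"])
    out = normalize_spectra(s, "total_area")
    np.testing.assert_allclose(out.intensities[0], out.intensities[1], rtol=1e-12)


def test_total_area_idempotent():
    _, spectra = simulate_cohort(small_config(seed=1))
    once = normalize_spectra(spectra, "total_area")
    twice = normalize_spectra(once, "total_area")
    np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-12)


def test_pqn_recovers_dilution_factors():
    ppm = np.arange(0.0, 6.0, 0.01)
    shape = np.exp(-0.5 * ((ppm - 1.3) / 0.1) ** 2) + 0.5
    factors = np.array([0.5, 1.0, 2.0])
    s = SpectrumSet(ppm, factors[:, None] * shape, ["a", "b", "c"])
    out = normalize_spectra(s, "pqn")
    for i in range(3):
        np.testing.assert_allclose(out.intensities[i], shape, atol=1e-10)


def test_zero_integral_names_subject():
    ppm = np.arange(0.0, 6.0, 0.01)
    s = SpectrumSet(ppm, np.vstack([np.ones(ppm.size), np.zeros(ppm.size)]), ["ok", "bad"])
    with pytest.raises(ValueError, match="bad"):
        normalize_spectra(s, "total_area")


def test_exclusion_window_must_be_inside_axis():
    with pytest.raises(ValueError, match="exclusion"):
        normalize_spectra(flat_spectra(hi=4.0), "total_area", (4.5, 5.0))


# --- binning ---------------------------------------------------------------


def test_unit_rectangle_bin():
    fm = bin_spectra(flat_spectra(), [BinDefinition("box", 1.0, 2.0)])
    np.testing.assert_allclose(fm.values, 1.0, atol=1e-12)
    assert fm.provenance == ["nmr_bin"]


def test_triangular_peak_area():
    ppm = np.arange(0.0, 4.0, 0.0005)
    h, center, half_base = 3.0, 2.0, 0.2
    tri = np.maximum(0.0, h * (1 - np.abs(ppm - center) / half_base))
    s = SpectrumSet(ppm, tri[None, :], ["a"])
    fm = bin_spectra(s, [BinDefinition("tri", 1.5, 2.5)])
    assert abs(fm.values[0, 0] - h * (2 * half_base) / 2) < 1e-6


def test_default_bin_table():
    by_name = {b.name: b for b in DEFAULT_BINS}
    assert (by_name["glyca"].ppm_lo, by_name["glyca"].ppm_hi) == (2.04, 2.05)
    assert (by_name["hdl"].ppm_lo, by_name["hdl"].ppm_hi) == (0.81, 0.87)
    assert (by_name["glutamine"].ppm_lo, by_name["glutamine"].ppm_hi) == (2.43, 2.47)


def test_bin_outside_axis_rejected():
    with pytest.raises(ValueError, match="does not overlap"):
        bin_spectra(flat_spectra(hi=4.0), [BinDefinition("off", 8.0, 9.0)])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(split=st.floats(min_value=1.01, max_value=1.99))
def test_bin_split_additivity(split):
    """Splitting a bin anywhere and summing the parts changes nothing."""
    rng = np.random.default_rng(0)
    ppm = np.arange(0.0, 4.0, 0.01)
    s = SpectrumSet(ppm, rng.random((3, ppm.size)), ["a", "b", "c"])
    whole = bin_spectra(s, [BinDefinition("w", 1.0, 2.0)]).values[:, 0]
    parts = bin_spectra(
        s, [BinDefinition("p1", 1.0, split), BinDefinition("p2", split, 2.0)]
    ).values
    np.testing.assert_allclose(parts.sum(axis=1), whole, atol=1e-9)


def test_uniform_bins_skip_water_window():
    bins = uniform_bins(0.0, 6.0, width=0.04)
    assert all(b.ppm_hi <= 4.5 or b.ppm_lo >= 5.0 for b in bins)
    assert len(bins) > 100


# --- feature integration ---------------------------------------------------


def make_features(seed=0, **overrides):
    cohort, spectra = simulate_cohort(small_config(seed=seed, **overrides))
    return cohort, bin_spectra(normalize_spectra(spectra))


def test_empty_clinical_vars_is_noop():
    cohort, nmr = make_features()
    fm = integrate_features(cohort, nmr, [])
    assert fm.feature_names == nmr.feature_names
    np.testing.assert_array_equal(fm.values, nmr.values)


def test_six_bins_plus_eleven_clinical_gives_seventeen():
    cohort, nmr = make_features()
    table_vars = [
        "bmi", "egfr", "alt", "ast", "hba1c", "ferritin", "cholesterol",
        "triglycerides", "hdl_cholesterol", "ldl_cholesterol", "lsm_kpa",
    ]
    fm = integrate_features(cohort, nmr, table_vars)
    assert fm.n_features == 17
    assert fm.provenance[:6] == ["nmr_bin"] * 6
    assert fm.provenance[6:] == ["clinical"] * 11
    assert fm.subject_ids == nmr.subject_ids  # order and count preserved


def test_missing_value_drop_and_impute():
    cohort, nmr = make_features()
    cohort = cohort.copy()
    cohort.loc[cohort.index[4], "hdl_cholesterol"] = np.nan
    dropped = integrate_features(cohort, nmr, ["hdl_cholesterol"], missing="drop")
    assert dropped.n_subjects == nmr.n_subjects - 1
    imputed = integrate_features(cohort, nmr, ["hdl_cholesterol"], missing="impute")
    assert imputed.n_subjects == nmr.n_subjects
    assert np.isfinite(imputed.values).all()


def test_subject_mismatch_lists_ids():
    cohort, nmr = make_features()
    bad = cohort.copy()
    bad.loc[bad.index[0], "subject_id"] = "INTRUDER"
    with pytest.raises(ValueError, match="INTRUDER"):
        integrate_features(bad, nmr, [])


# --- scaling ---------------------------------------------------------------


def test_unit_variance_scaling_exact():
    cohort, nmr = make_features()
    fm = integrate_features(cohort, nmr, ["triglycerides"])
    scaled = scale_features(fm, "unit_variance")
    assert np.abs(scaled.values.mean(axis=0)).max() < 1e-12
    assert np.abs(scaled.values.std(axis=0, ddof=1) - 1).max() < 1e-12
    assert scaled.scaling == "unit_variance"


def test_constant_column_dropped_with_warning(caplog):
    fm = FeatureMatrix(
        np.column_stack([np.arange(5.0), np.full(5, 7.0)]),
        ["varies", "constant"],
        ["nmr_bin", "clinical"],
        [f"s{i}" for i in range(5)],
    )
    with caplog.at_level("WARNING", logger="seropls"):
        scaled = scale_features(fm)
    assert scaled.feature_names == ["varies"]
    assert "constant" in caplog.text


def test_all_constant_matrix_rejected():
    fm = FeatureMatrix(np.ones((4, 2)), ["a", "b"], ["nmr_bin"] * 2, list("wxyz"))
    with pytest.raises(ValueError, match="zero variance"):
        scale_features(fm)


@pytest.mark.parametrize("method", ["unit_variance", "pareto", "center_only"])
def test_scaling_inverts_exactly(method):
    cohort, nmr = make_features(seed=5)
    fm = integrate_features(cohort, nmr, ["bmi", "alt"])
    restored = scale_features(fm, method).inverse_transform()
    np.testing.assert_allclose(restored.values, fm.values, atol=1e-10)
    assert restored.scaling == "raw"


def test_fit_scaler_uses_given_rows_only(rng):
    X = rng.standard_normal((20, 4))
    c1, s1 = fit_scaler(X[:15])
    X2 = X.copy()
    X2[17] += 1e6  # pollute a row outside the training slice
    c2, s2 = fit_scaler(X2[:15])
    assert np.array_equal(c1, c2) and np.array_equal(s1, s2)
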