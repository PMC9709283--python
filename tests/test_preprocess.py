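"""Normalization (medFC, QC-LOESS) and quality-assurance filtering."""
import numpy as np
import pytest

from metabopair import (
    FeatureTableError,
    SimulationSpec,
    cv_percent,
    loess_qc_correct,
    medfc_normalize,
    qa_filter,
    simulate_study,
)
from metabopair.preprocess import QaReport
from conftest import build_table, qc_study_records


# -- cv_percent -------------------------------------------------------------


def test_cv_percent_closed_form_and_scale_invariance():
    assert cv_percent([1.0, 1.0, 1.0]) == 0.0
    assert cv_percent([90.0, 100.0, 110.0]) == pytest.approx(10.0)
    v = np.array([3.0, 5.0, 9.0, 4.0])
    assert cv_percent(7.3 * v) == pytest.approx(cv_percent(v))
    assert np.isnan(cv_percent([0.0, 0.0]))
    with pytest.raises(ValueError):
        cv_percent([1.0])


# -- medFC ------------------------------------------------------------------


def test_medfc_exact_scaling_recovers_reference():
    recs = qc_study_records(0, 6)
    base = np.array([[10, 20, 30], [5, 50, 500], [1, 2, 3], [8, 8, 8], [4, 9, 16]], float)
    X = np.column_stack([base[:, [0, 1, 2]], 2.0 * base[:, 0], base[:, 1], base[:, 2]])
    table = build_table(X, recs)
    normalized, factors = medfc_normalize(table)
    # column S003 is exactly twice the profile of S000
    assert factors["S003"] / factors["S000"] == pytest.approx(2.0)
    np.testing.assert_allclose(
        normalized.intensities["S003"], normalized.intensities["S000"]
    )


def test_medfc_identity_when_all_columns_equal():
    recs = qc_study_records(0, 4)
    X = np.tile(np.array([[3.0], [7.0], [11.0]]), (1, 4))
    normalized, factors = medfc_normalize(build_table(X, recs))
    np.testing.assert_allclose(factors.to_numpy(), 1.0)
    np.testing.assert_allclose(normalized.intensities.to_numpy(), X)


def test_medfc_recovers_simulated_dilution_factors():
    rng = np.random.default_rng(4)
    recs = qc_study_records(0, 6)
    profile = np.exp(rng.normal(3, 1, size=300))
    dilution = np.array([0.5, 1.0, 2.0, 0.5, 1.0, 2.0])
    noise = np.exp(rng.normal(0, 0.01, size=(300, 6)))
    X = profile[:, None] * dilution[None, :] * noise
    _, factors = medfc_normalize(build_table(X, recs))
    rel = factors.to_numpy() / dilution
    rel /= rel.mean()  # factors are defined up to a global constant
    np.testing.assert_allclose(rel, 1.0, rtol=0.01)


def test_medfc_idempotent():
    """Second-pass factors stay near 1; residual drift of the median reference
    profile bounds how far they can move."""
    table, _ = simulate_study(
        SimulationSpec(n_subjects=10, n_features=200, noise_sd=0.1, seed=6)
    )
    once, _ = medfc_normalize(table)
    twice, factors2 = medfc_normalize(once)
    np.testing.assert_allclose(factors2.to_numpy(), 1.0, atol=0.05)
    np.testing.assert_allclose(
        twice.intensities.to_numpy(), once.intensities.to_numpy(), rtol=0.05
    )


def test_medfc_errors():
    recs = qc_study_records(0, 2)
    X = np.array([[1.0, 0.0], [2.0, 0.0]])
    with pytest.raises(FeatureTableError, match="no positive"):
        medfc_normalize(build_table(X, recs))


# -- LOESS QC correction ----------------------------------------------------


def _drifted_table(drift_amplitude, seed=13, noise_sd=0.05):
    spec = SimulationSpec(
        n_subjects=10, n_features=80, n_affected=0, noise_sd=noise_sd,
        drift_amplitude=drift_amplitude, zero_rate=0.0, seed=seed,
    )
    return simulate_study(spec)[0]


def test_loess_flat_qc_leaves_table_unchanged():
    table = _drifted_table(0.0, noise_sd=1e-9)
    corrected, skipped = loess_qc_correct(table, span=0.75)
    assert skipped == []
    np.testing.assert_allclose(
        corrected.intensities.to_numpy(), table.intensities.to_numpy(), rtol=1e-6
    )


def test_loess_reduces_qc_cv_under_drift():
    table = _drifted_table(1.0)  # 2-fold peak-to-trough drift
    corrected, _ = loess_qc_correct(table, span=0.75)
    qc_ids = table.injection_ids("qc")
    before = table.intensities[qc_ids].apply(lambda r: cv_percent(r.to_numpy()), axis=1)
    after = corrected.intensities[qc_ids].apply(lambda r: cv_percent(r.to_numpy()), axis=1)
    assert (after < before).mean() >= 0.95


def test_loess_requires_enough_qcs():
    recs = qc_study_records(2, 6)
    with pytest.raises(FeatureTableError, match="4 QC"):
        loess_qc_correct(build_table(np.ones((3, 8)), recs))


def test_loess_passes_through_all_zero_qc_features():
    table = _drifted_table(0.5)
    X = table.intensities.copy()
    X.loc["F0001", table.injection_ids("qc")] = 0.0
    table = table.with_intensities(X, "zeroed")
    corrected, skipped = loess_qc_correct(table)
    assert skipped == ["F0001"]
    np.testing.assert_array_equal(
        corrected.intensities.loc["F0001"], table.intensities.loc["F0001"]
    )


# -- QA filter --------------------------------------------------------------


def _qa_table(qc_rows, study_rows):
    """Build a table with explicit QC and study intensities per feature."""
    n_qc = len(qc_rows[0])
    n_study = len(study_rows[0])
    recs = qc_study_records(n_qc, n_study)
    X = np.column_stack([np.asarray(qc_rows, float), np.asarray(study_rows, float)])
    return build_table(X, recs)


def test_qa_filter_cv_and_zero_rules():
    table = _qa_table(
        qc_rows=[[90, 100, 110], [50, 100, 150], [100, 100, 100]],
        study_rows=[
            [1] * 10,
            [1] * 10,
            [0] * 7 + [1] * 3,  # 70% zeros -> removed
        ],
    )
    filtered, report = qa_filter(table, cv_max_pct=30.0, zero_max_pct=60.0)
    rep = report.table
    assert rep.loc["F000", "qc_cv_pct"] == pytest.approx(10.0)
    assert bool(rep.loc["F000", "retained"])  # CV 10% passes
    assert rep.loc["F001", "reason"] == "cv_fail"  # CV 50%
    assert rep.loc["F002", "reason"] == "zero_fail"  # 70% zeros
    assert filtered.n_features == 1


def test_qa_filter_boundaries_strict():
    """CV of exactly the threshold is removed; zero% exactly at threshold kept."""
    qc_exact_30 = [100 - 30, 100, 100 + 30]  # sd = 30, mean = 100 -> CV 30%
    table = _qa_table(
        qc_rows=[qc_exact_30, [100, 100, 100], [100, 100, 100]],
        study_rows=[[1] * 10, [0] * 6 + [1] * 4, [1] * 10],  # 60% zeros kept
    )
    _, report = qa_filter(table, cv_max_pct=30.0, zero_max_pct=60.0)
    assert not bool(report.table.loc["F000", "retained"])  # CV == 30 -> removed
    assert bool(report.table.loc["F001", "retained"])  # zeros == 60% -> kept
    assert bool(report.table.loc["F002", "retained"])
    # constant QC -> CV 0 -> retained
    assert report.table.loc["F002", "qc_cv_pct"] == 0.0


def test_qa_monotone_in_cv_threshold():
    rng = np.random.default_rng(3)
    qc = rng.lognormal(3, 0.4, size=(40, 5))
    study = rng.lognormal(3, 0.4, size=(40, 8))
    table = _qa_table(qc.tolist(), study.tolist())
    retained = {}
    for cv_max in (40.0, 30.0, 20.0, 10.0):
        _, rep = qa_filter(table, cv_max_pct=cv_max)
        retained[cv_max] = set(rep.retained_ids)
    assert retained[10.0] <= retained[20.0] <= retained[30.0] <= retained[40.0]


def test_qa_counts_conserved(small_study):
    table, _ = small_study
    filtered, report = qa_filter(table)
    assert len(report.retained_ids) + len(report.removed_ids) == table.n_features
    assert filtered.n_features == len(report.retained_ids)
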