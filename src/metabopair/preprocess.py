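"""Normalization and quality-assurance filtering.

Two normalizations run before any statistics: median fold change (medFC)
scaling, which removes per-injection dilution by dividing each injection by
the median of its feature-wise fold changes against a median reference
profile; and QC-based LOESS drift correction (QC-RLSC), which fits a smooth
curve to each feature's pooled-QC intensities along the injection order and
divides it out. Features are then filtered on QC coefficient of variation
and on the fraction of zero intensities among study samples.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import FeatureTable, FeatureTableError


def cv_percent(values: np.ndarray | list[float]) -> float:
    """Coefficient of variation, percent: 100 * sample SD (n-1) / mean.

    Undefined (NaN) when the mean is not positive.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("cv_percent needs at least 2 values")
    mean = v.mean()
    if mean <= 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / mean)


def medfc_normalize(table: FeatureTable) -> tuple[FeatureTable, pd.Series]:
    """Median-fold-change normalization against the median study profile.

    The reference is the feature-wise median over study injections; each
    injection's scale factor is the median, over features positive in both,
    of intensity/reference. Every column (study, QC, blank) is divided by
    its own factor. Returns the normalized table and the factors.
    """
    if table.n_injections < 2:
        raise FeatureTableError("medFC needs at least 2 injections")
    study_ids = table.injection_ids("study")
    if not study_ids:
        raise FeatureTableError("medFC needs study injections for the reference profile")
    X = table.intensities
    reference = X[study_ids].median(axis=1)
    factors = {}
    for inj in X.columns:
        col = X[inj]
        shared = (col > 0) & (reference > 0)
        if not shared.any():
            raise FeatureTableError(
                f"injection {inj!r} shares no positive features with the reference profile"
            )
        factors[inj] = float((col[shared] / reference[shared]).median())
    factors = pd.Series(factors, name="medfc_factor")
    normalized = X.div(factors, axis=1)
    out = table.with_intensities(
        normalized, f"medFC normalization (factors {factors.min():.3g}-{factors.max():.3g})"
    )
    return out, factors


def loess_qc_correct(
    table: FeatureTable, span: float = 0.75
) -> tuple[FeatureTable, list[str]]:
    """Per-feature LOESS drift correction anchored on pooled-QC injections.

    For each feature, a LOESS curve of QC intensity versus injection order is
    fitted and evaluated at every injection's order (linear interpolation
    between QC orders, clamped outside); the corrected intensity is
    raw * median(QC raw) / fitted. Features whose QC values are all zero
    pass through unchanged and are returned in the skipped list.
    """
    qc_ids = table.injection_ids("qc")
    if len(qc_ids) < 4:
        raise FeatureTableError(
            f"LOESS drift correction needs >= 4 QC injections, found {len(qc_ids)}; "
            "skip the stage explicitly if the run carries fewer"
        )
    order = table.injection_frame()["injection_order"]
    qc_order = order[qc_ids].to_numpy(dtype=float)
    study_ids = table.injection_ids("study")
    if study_ids:
        smin, smax = order[study_ids].min(), order[study_ids].max()
        if qc_order.min() > smin or qc_order.max() < smax:
            raise FeatureTableError(
                "QC injections do not span the study injections' order range"
            )
    all_order = order.to_numpy(dtype=float)

    X = table.intensities.to_numpy(dtype=float)
    qc_cols = [table.intensities.columns.get_loc(c) for c in qc_ids]
    corrected = X.copy()
    skipped: list[str] = []
    sort_idx = np.argsort(qc_order)
    qx = qc_order[sort_idx]
    for j, fid in enumerate(table.intensities.index):
        qy = X[j, qc_cols][sort_idx]
        if not (qy > 0).any():
            skipped.append(fid)
            continue
        fitted_at_qc = lowess(qy, qx, frac=span, return_sorted=False)
        # interpolate fitted curve to every injection order, clamped outside
        fitted = np.interp(all_order, qx, fitted_at_qc)
        fitted = np.maximum(fitted, 1e-12 * np.median(qy[qy > 0]))
        corrected[j, :] = X[j, :] * np.median(qy) / fitted
    out_df = pd.DataFrame(
        corrected, index=table.intensities.index, columns=table.intensities.columns
    )
    note = f"LOESS QC drift correction (span={span}, {len(skipped)} all-zero-QC features skipped)"
    return table.with_intensities(out_df, note), skipped


@dataclass
class QaReport:
    """Per-feature QC CV and zero-fraction with the retain/drop decision."""

    table: pd.DataFrame  # columns: qc_cv_pct, zero_pct, retained, reason

    @property
    def retained_ids(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])

    @property
    def removed_ids(self) -> list[str]:
        return list(self.table.index[~self.table["retained"]])


def qa_filter(
    table: FeatureTable, cv_max_pct: float = 30.0, zero_max_pct: float = 60.0
) -> tuple[FeatureTable, QaReport]:
    """Retain features with QC CV strictly below ``cv_max_pct`` and a
    zero-percentage (over study injections) not above ``zero_max_pct``.

    Both boundaries follow the published wording: CV must be < 30% (a CV of
    exactly 30% is removed) and features are removed when the zero fraction
    is > 60% (exactly 60% is retained). An undefined CV (all-zero QC) fails
    the CV criterion.
    """
    qc_ids = table.injection_ids("qc")
    study_ids = table.injection_ids("study")
    if len(qc_ids) < 2:
        raise FeatureTableError("QA filter needs >= 2 QC injections to compute CVs")
    if not study_ids:
        raise FeatureTableError("QA filter needs study injections for the zero fraction")

    qc = table.intensities[qc_ids]
    study = table.intensities[study_ids]
    cv = qc.apply(lambda row: cv_percent(row.to_numpy()), axis=1)
    zero_pct = 100.0 * (study == 0).sum(axis=1) / len(study_ids)

    cv_ok = cv < cv_max_pct  # NaN compares False -> removed
    zero_ok = zero_pct <= zero_max_pct
    retained = cv_ok & zero_ok
    reason = np.where(retained, "pass", np.where(~cv_ok, "cv_fail", "zero_fail"))
    report = QaReport(
        pd.DataFrame(
            {
                "qc_cv_pct": cv,
                "zero_pct": zero_pct,
                "retained": retained,
                "reason": reason,
            },
            index=table.intensities.index,
        )
    )
    filtered = table.select_features(
        report.retained_ids,
        f"QA filter (CV<{cv_max_pct}%, zeros<={zero_max_pct}%): "
        f"{len(report.retained_ids)}/{table.n_features} retained",
    )
    return filtered, report
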