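"""End-to-end orchestration of one comparison.

Stage order follows the published workflow: medFC normalization, QC-LOESS
drift correction, QA filtering, paired volcano pre-selection, then — on the
volcano-selected features only — PCA, OPLS-DA with validation, the VIP /
jack-knife / fold-change cascade, and adduct-based annotation. Every stage
appends a machine-readable audit entry with its counts and decisions.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import annotate_features
from .config import PipelineConfig
from .containers import ComparisonSpec, FeatureTable, PairedData, subset_comparison
from .multivariate import (
    CvResult, OplsModel, PcaModel, ValidationReport,
    fit_pca, scale_matrix, select_n_ortho, validate_model,
)
from .preprocess import QaReport, loess_qc_correct, medfc_normalize, qa_filter
from .selection import (
    VipResult, jackknife_ci, select_discriminant, verify_peak_checklist, vip_scores,
)
from .univariate import VolcanoResult, volcano_analysis


@dataclass
class PipelineResult:
    """Everything one comparison produces, stage by stage."""

    comparison: str
    config: PipelineConfig
    qa_report: QaReport
    medfc_factors: pd.Series
    paired: PairedData
    volcano: VolcanoResult
    selected_feature_ids: list[str]  # volcano-selected, input to multivariate
    multivariate_status: str  # "ok" | "skipped: <reason>"
    pca: Optional[PcaModel] = None
    opls: Optional[OplsModel] = None
    cv: Optional[CvResult] = None
    validation: Optional[ValidationReport] = None
    n_ortho: Optional[int] = None
    vip_result: Optional[VipResult] = None
    discriminant: Optional[pd.DataFrame] = None
    annotations: Optional[pd.DataFrame] = None
    checklist: Optional[pd.DataFrame] = None
    audit_log: list[dict] = field(default_factory=list)


def run_pipeline(
    table: FeatureTable,
    spec: ComparisonSpec,
    config: PipelineConfig | None = None,
    library: Optional[pd.DataFrame] = None,
) -> PipelineResult:
    """Run the full paired differential workflow for one comparison.

    With fewer than 2 volcano-selected features the multivariate stage is
    skipped with an explicit status (a single selected variable is still
    annotated, mirroring the between-dialysate comparison of the study).
    """
    cfg = config or PipelineConfig()
    audit: list[dict] = []

    def log(stage: str, **info) -> None:
        audit.append({"stage": stage, **info})

    log("input", n_features=table.n_features, n_injections=table.n_injections)

    # 1. normalization
    if cfg.apply_medfc:
        table, factors = medfc_normalize(table)
        log("medfc", factor_min=float(factors.min()), factor_max=float(factors.max()))
    else:
        factors = pd.Series(1.0, index=[i.injection_id for i in table.injections])
        log("medfc", skipped=True)
    if cfg.apply_loess:
        table, loess_skipped = loess_qc_correct(table, span=cfg.loess_span)
        log("loess", span=cfg.loess_span, all_zero_qc_features=len(loess_skipped))
    else:
        log("loess", skipped=True)

    # 2. quality assurance
    n_before = table.n_features
    table, qa = qa_filter(table, cv_max_pct=cfg.cv_max_pct, zero_max_pct=cfg.zero_max_pct)
    reasons = qa.table.loc[~qa.table["retained"], "reason"].value_counts().to_dict()
    log("qa_filter", n_in=n_before, n_retained=table.n_features, removed_by=reasons)

    # 3. paired volcano
    paired = subset_comparison(table, spec)
    log(
        "pairing", comparison=spec.name, n_pairs=paired.n_pairs,
        dropped_subjects=paired.dropped_subjects,
    )
    volcano = volcano_analysis(
        paired,
        abs_log2fc_min=cfg.abs_log2fc_min,
        alpha=cfg.alpha,
        shapiro_alpha=cfg.shapiro_alpha,
        use_adjusted_p=cfg.use_adjusted_p,
        zero_impute=cfg.zero_impute,
    )
    selected = volcano.selected_ids
    log("volcano", n_tested=int(volcano.table["p_raw"].notna().sum()), n_selected=len(selected))

    result = PipelineResult(
        comparison=spec.name, config=cfg, qa_report=qa, medfc_factors=factors,
        paired=paired, volcano=volcano, selected_feature_ids=selected,
        multivariate_status="pending", audit_log=audit,
    )

    # 4. multivariate on volcano-selected features only
    if len(selected) < 2:
        result.multivariate_status = (
            f"skipped: only {len(selected)} volcano-selected feature(s); "
            "multivariate analysis not performed"
        )
        log("multivariate", status=result.multivariate_status)
    else:
        # samples = paired injections of both groups; class = group label
        A = paired.a.loc[selected].T.to_numpy(dtype=float)  # subjects x features
        B = paired.b.loc[selected].T.to_numpy(dtype=float)
        X_raw = np.vstack([A, B])
        y = [spec.label_a] * A.shape[0] + [spec.label_b] * B.shape[0]
        scaled = scale_matrix(X_raw, scaling=cfg.scaling, feature_ids=selected)
        if scaled.dropped:
            log("scaling", dropped_zero_variance=scaled.dropped)
        n_pca = min(2, scaled.X.shape[0] - 1, scaled.X.shape[1])
        result.pca = fit_pca(scaled, n_components=n_pca)
        n_ortho, q2_profile = select_n_ortho(
            scaled.X, y, max_ortho=cfg.max_orthogonal, folds=cfg.n_folds, seed=cfg.seed
        )
        result.n_ortho = n_ortho
        model, cv, report = validate_model(
            scaled.X, y, n_ortho=n_ortho, folds=cfg.n_folds,
            n_permutations=cfg.n_permutations, seed=cfg.seed,
            q2_threshold=cfg.q2_threshold, alpha=cfg.alpha,
        )
        result.opls, result.cv, result.validation = model, cv, report
        result.multivariate_status = "ok"
        log(
            "oplsda", n_ortho=n_ortho, q2_profile=q2_profile, r2y=report.r2y, q2=report.q2,
            cv_anova_p=report.cv_anova_p, perm_p_q2=report.permutation.p_q2,
            overall_valid=report.overall_valid,
        )

        # 5. VIP cascade
        kept = scaled.feature_ids  # zero-variance columns were dropped
        vip = vip_scores(model, mode=cfg.vip_mode)
        ci_low, ci_high = jackknife_ci(cv, vip, mode=cfg.vip_mode)
        fc = (
            paired.b.loc[kept].mean(axis=1) / paired.a.loc[kept].mean(axis=1)
        ).to_numpy(dtype=float)
        vips = VipResult(
            pd.DataFrame(
                {"vip": vip, "ci_low": ci_low, "ci_high": ci_high, "fc": fc},
                index=pd.Index(kept, name="feature_id"),
            )
        )
        result.vip_result = vips
        result.discriminant = select_discriminant(
            vips, top_n=cfg.top_n, vip_min=cfg.vip_min, fc_min=cfg.fc_min
        )
        log("selection", n_candidates=len(kept), n_selected=len(result.discriminant))

    # 6. annotation of the final variables (or the lone volcano variable)
    to_annotate = (
        list(result.discriminant.index)
        if result.discriminant is not None
        else selected
    )
    if library is not None and to_annotate:
        feats = table.feature_frame()
        mz_pairs = [(fid, float(feats.loc[fid, "mz"])) for fid in to_annotate]
        result.annotations = annotate_features(
            mz_pairs, library, adducts=tuple(cfg.adducts), tolerance_ppm=cfg.ppm_tolerance
        )
        log(
            "annotation", n_features=len(to_annotate),
            n_hits=int((result.annotations["msi_level"] < 4).sum()),
        )
    qc_ids = table.injection_ids("qc")
    checklist_input = (
        result.discriminant
        if result.discriminant is not None
        else pd.DataFrame(index=pd.Index(to_annotate, name="feature_id"))
    )
    result.checklist = verify_peak_checklist(
        checklist_input, table.feature_frame(), table.intensities[qc_ids]
    )
    log("done", status=result.multivariate_status)
    return result


def write_result(result: PipelineResult, out_dir: str | Path) -> None:
    """Write per-stage tables, a JSON summary and the audit log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.qa_report.table.to_csv(out / "qa_report.tsv", sep="\t")
    result.volcano.table.to_csv(out / "volcano.tsv", sep="\t")
    if result.vip_result is not None:
        result.vip_result.table.to_csv(out / "vip.tsv", sep="\t")
    if result.discriminant is not None:
        result.discriminant.to_csv(out / "selected_variables.tsv", sep="\t")
    if result.annotations is not None:
        result.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    if result.checklist is not None:
        result.checklist.to_csv(out / "verify_peak_checklist.tsv", sep="\t", index=False)
    summary = {
        "comparison": result.comparison,
        "n_pairs": result.paired.n_pairs,
        "n_volcano_selected": len(result.selected_feature_ids),
        "multivariate_status": result.multivariate_status,
    }
    if result.validation is not None:
        summary.update(
            r2y=result.validation.r2y,
            q2=result.validation.q2,
            cv_anova_p=result.validation.cv_anova_p,
            permutation_p_q2=result.validation.permutation.p_q2,
            permutation_p_r2=result.validation.permutation.p_r2,
            n_ortho=result.n_ortho,
            overall_valid=result.validation.overall_valid,
        )
    if result.discriminant is not None:
        summary["n_discriminant"] = len(result.discriminant)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (out / "audit_log.json").write_text(json.dumps(result.audit_log, indent=2, default=str))
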