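"""VIP scores, jack-knife confidence intervals and the selection cascade.

Discriminant variables are the top ``top_n`` features ranked by variable
importance in projection (VIP) that additionally show VIP > 1, a jack-knife
confidence interval excluding zero, and a two-sided fold change above 1.2.
The VIP normalization makes the mean squared VIP equal one, so the sum of
squared VIPs equals the number of features.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .multivariate import CvResult, OplsModel


def vip_scores(model: OplsModel, mode: str = "total") -> np.ndarray:
    """VIP per feature from a fitted OPLS-DA model.

    VIP_j = sqrt( p * sum_a s_a (w_aj/||w_a||)^2 / sum_a s_a ), where the
    predictive component is weighted by the y sum of squares it explains and
    — in ``total`` mode — orthogonal components contribute weighted by the X
    sum of squares they capture. ``predictive`` mode uses the predictive
    component only. Either normalization keeps sum(VIP^2) = p.
    """
    p = model.w.shape[0]
    comps = [(model.ssy_pred, model.w)]
    if mode == "total":
        for a in range(model.n_ortho):
            comps.append((float(model.ssx_ortho[a]), model.W_o[:, a]))
    elif mode != "predictive":
        raise ValueError(f"unknown VIP mode {mode!r}")
    total = sum(s for s, _ in comps)
    if total <= 0:
        raise ValueError("model explains no variance; VIP undefined")
    acc = np.zeros(p)
    for s, w in comps:
        nw = np.linalg.norm(w)
        if nw > 0:
            acc += s * (w / nw) ** 2
    return np.sqrt(p * acc / total)


def jackknife_ci(
    cv: CvResult, full_vip: np.ndarray, confidence: float = 0.95, mode: str = "total"
) -> tuple[np.ndarray, np.ndarray]:
    """Martens' jack-knife interval for VIP from cross-validation sub-models.

    SE_j^2 = ((G-1)/G) * sum_g (VIP_jg - VIP_j)^2 with VIP_j the full-model
    score; the interval is VIP_j +/- t_{1-alpha/2, G-1} * SE_j. Sub-models
    that failed to fit are simply absent from ``cv.submodels`` (G reduced).
    """
    sub_vips = []
    for sub in cv.submodels:
        try:
            sub_vips.append(vip_scores(sub, mode=mode))
        except ValueError:
            continue
    G = len(sub_vips)
    if G < 3:
        raise ValueError(f"jack-knife needs >= 3 sub-models, got {G}")
    V = np.vstack(sub_vips)  # G x p; VIP >= 0, no sign alignment needed
    se = np.sqrt((G - 1) / G * ((V - full_vip) ** 2).sum(axis=0))
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=G - 1)
    return full_vip - tcrit * se, full_vip + tcrit * se


@dataclass
class VipResult:
    """Per-feature VIP, jack-knife CI and raw-scale fold change (b over a)."""

    table: pd.DataFrame  # columns: vip, ci_low, ci_high, fc


def two_sided_fc(fc: float) -> float:
    """Fold change magnitude regardless of direction: max(FC, 1/FC)."""
    return max(fc, 1.0 / fc) if fc > 0 else float("inf")


def select_discriminant(
    vips: VipResult,
    top_n: int = 30,
    vip_min: float = 1.0,
    fc_min: float = 1.2,
) -> pd.DataFrame:
    """The discriminant-variable cascade.

    Features are ranked by VIP descending (feature_id breaking ties) and the
    cut to the first ``top_n`` happens before thresholding, so at most
    ``top_n`` variables can be selected. Within those, a variable is kept
    when VIP > vip_min, its jack-knife CI excludes zero (strictly positive
    or strictly negative interval; a degenerate [0, 0] interval counts as
    including zero), and its two-sided fold change exceeds ``fc_min``.
    """
    df = vips.table.copy()
    key = pd.DataFrame({"v": -df["vip"], "id": df.index}, index=df.index)
    ranked = df.loc[key.sort_values(["v", "id"], kind="mergesort").index]
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    head = ranked.head(top_n)
    ci_excludes_zero = (head["ci_low"] > 0) | (head["ci_high"] < 0)
    fc2 = head["fc"].map(two_sided_fc)
    keep = (head["vip"] > vip_min) & ci_excludes_zero & (fc2 > fc_min)
    out = head[keep].copy()
    out["two_sided_fc"] = fc2[keep]
    out.index.name = "feature_id"
    return out


def verify_peak_checklist(
    selected: pd.DataFrame, table_features: pd.DataFrame, qc_intensities: pd.DataFrame
) -> pd.DataFrame:
    """Manual-review checklist for selected features.

    One row per selected feature with its m/z, retention time and pooled-QC
    intensity profile in injection order, for eyeballing peak shape and
    retention-time stability in the raw data. A report artifact, not an
    automated classifier; an empty selection yields an empty checklist.
    """
    rows = []
    for fid in selected.index:
        mz = table_features.loc[fid, "mz"] if fid in table_features.index else np.nan
        rt = table_features.loc[fid, "rt"] if fid in table_features.index else np.nan
        profile = (
            qc_intensities.loc[fid].to_list() if fid in qc_intensities.index else []
        )
        rows.append(dict(feature_id=fid, mz=mz, rt=rt, qc_profile=profile))
    return pd.DataFrame(rows, columns=["feature_id", "mz", "rt", "qc_profile"])
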