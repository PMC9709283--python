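"""Paired volcano pre-selection of molecular features.

For each feature, the paired log2 fold change (group b over group a) is
combined with a paired significance test — Student's t when the paired
differences look normal by Shapiro-Wilk, Wilcoxon signed-rank otherwise —
and p-values are adjusted across features by Benjamini-Hochberg. Features
pass when |log2FC| > 1 and the (adjusted) p-value is < 0.05, both strict.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import PairedData


@dataclass
class VolcanoResult:
    """Per-feature volcano statistics and the selection flag."""

    table: pd.DataFrame  # log2fc, test_used, shapiro_p, p_raw, p_adj, selected

    @property
    def selected_ids(self) -> list[str]:
        sel = self.table[self.table["selected"]]
        order = sel.reindex(
            sel["log2fc"].abs().sort_values(ascending=False, kind="mergesort").index
        )
        # deterministic: |log2fc| descending, feature_id breaking ties
        key = pd.DataFrame({"a": -order["log2fc"].abs(), "id": order.index})
        return list(key.sort_values(["a", "id"], kind="mergesort")["id"])


def impute_zeros(a: np.ndarray, b: np.ndarray, mode: str = "half_min") -> tuple[np.ndarray, np.ndarray]:
    """Replace zeros before forming ratios.

    ``half_min`` substitutes half the smallest positive value of the feature
    across both groups; ``unit_offset`` adds 1 everywhere. All-zero features
    cannot be imputed and must be handled by the caller.
    """
    stacked = np.concatenate([a, b])
    positive = stacked[stacked > 0]
    if positive.size == 0:
        raise ValueError("all-zero feature cannot be imputed")
    if mode == "half_min":
        repl = positive.min() / 2.0
        return np.where(a > 0, a, repl), np.where(b > 0, b, repl)
    if mode == "unit_offset":
        return a + 1.0, b + 1.0
    raise ValueError(f"unknown imputation mode {mode!r}")


def paired_log2fc(a: np.ndarray, b: np.ndarray) -> float:
    """log2 of the ratio of paired-group means, b over a (zeros pre-imputed)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired_log2fc needs >= 2 pairs of equal length")
    return float(np.log2(b.mean() / a.mean()))


def choose_test(differences: np.ndarray, normality_alpha: float = 0.05) -> tuple[str, float]:
    """Shapiro-Wilk routing: paired t when differences look normal, else Wilcoxon.

    Returns (test name, Shapiro p). Constant differences are degenerate for
    Shapiro-Wilk and are routed to Wilcoxon with shapiro_p = NaN.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValueError("choose_test needs >= 3 differences")
    if np.allclose(d, d[0]):
        return "wilcoxon", float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shapiro_p = float(stats.shapiro(d).pvalue)
    return ("paired_t" if shapiro_p >= normality_alpha else "wilcoxon"), shapiro_p


def paired_test(a: np.ndarray, b: np.ndarray, test: str) -> float:
    """Two-sided p-value of the chosen paired test on b - a.

    Degenerate inputs follow explicit conventions: identical groups give
    p = 1; a constant non-zero difference has zero variance, treated as
    maximal evidence (p -> 0) for the t-test.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if np.allclose(d, 0):
        return 1.0
    if test == "paired_t":
        if np.allclose(d, d[0]):  # zero variance, nonzero shift
            return 0.0
        return float(stats.ttest_rel(b, a).pvalue)
    if test == "wilcoxon":
        nz = d[d != 0]
        if nz.size == 0:
            return 1.0
        exact = nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(
                nz, method="exact" if exact else "approx", correction=not exact
            )
        return float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, same order as input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano_analysis(
    paired: PairedData,
    abs_log2fc_min: float = 1.0,
    alpha: float = 0.05,
    shapiro_alpha: float = 0.05,
    use_adjusted_p: bool = True,
    zero_impute: str = "half_min",
) -> VolcanoResult:
    """Run the full volcano stage on paired per-subject intensities.

    All-zero features are excluded (flagged with NaN statistics and never
    selected). Selection is strict on both criteria: |log2FC| > threshold
    and p < alpha, where p is BH-adjusted by default.
    """
    rows = {}
    for fid in paired.a.index:
        a = paired.a.loc[fid].to_numpy(dtype=float)
        b = paired.b.loc[fid].to_numpy(dtype=float)
        if not ((a > 0).any() or (b > 0).any()):
            rows[fid] = dict(
                log2fc=np.nan, test_used="excluded", shapiro_p=np.nan, p_raw=np.nan
            )
            continue
        a_i, b_i = impute_zeros(a, b, mode=zero_impute)
        lfc = paired_log2fc(a_i, b_i)
        test, shapiro_p = choose_test(b_i - a_i, normality_alpha=shapiro_alpha)
        p_raw = paired_test(a_i, b_i, test)
        rows[fid] = dict(log2fc=lfc, test_used=test, shapiro_p=shapiro_p, p_raw=p_raw)
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(paired.a.index)

    valid = df["p_raw"].notna()
    p_adj = pd.Series(np.nan, index=df.index)
    if valid.any():
        p_adj[valid] = bh_adjust(df.loc[valid, "p_raw"].to_numpy())
    df["p_adj"] = p_adj
    p_for_sel = df["p_adj"] if use_adjusted_p else df["p_raw"]
    df["selected"] = (df["log2fc"].abs() > abs_log2fc_min) & (p_for_sel < alpha)
    df["selected"] = df["selected"].fillna(False)
    df.index.name = "feature_id"
    return VolcanoResult(df)


def volcano_select(
    result: VolcanoResult, abs_log2fc_min: float = 1.0, alpha: float = 0.05
) -> list[str]:
    """Re-apply the strict selection thresholds and return ordered feature ids."""
    df = result.table
    sel = df[(df["log2fc"].abs() > abs_log2fc_min) & (df["p_adj"] < alpha)]
    key = pd.DataFrame({"a": -sel["log2fc"].abs(), "id": sel.index})
    return list(key.sort_values(["a", "id"], kind="mergesort")["id"])
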