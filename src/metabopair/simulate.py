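"""Synthetic crossover study generator with known ground truth.

Emulates the design the pipeline targets: each subject is dialyzed once per
arm (acetate AD / citrate CD) with plasma drawn at paired timepoints, and
the injection sequence carries leading QC pools, interleaved QC pools every
few study samples, and terminal blanks.

Intensity model (all terms multiplicative / log-normal):

    I(f, i) = exp(baseline_f + subject_(f,s) + effect_f * 1[post] + eps) * drift(order_i)

QC pools hold the pooled baseline profile with small replicate noise; a
smooth drift profile multiplies everything; study intensities are then
zero-censored at a fixed rate to mimic below-detection dropouts. Affected
features carry a known post/pre fold change, so every downstream stage can
be scored against ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import Feature, FeatureTable, InjectionRecord
from .io import default_library_path, read_compound_library


@dataclass
class SimulationSpec:
    """Parameters of the synthetic crossover study.

    Defaults mirror the study scale: 21 subjects, two crossover arms,
    paired pre/post sampling, 500 features, 5 leading QC pools and a QC
    every 6 study injections (the run interleaved QCs every 5-7 samples).
    Log-scale spreads are conventions for plasma LC-MS profiles, not fits.
    """

    n_subjects: int = 21
    arms: Sequence[str] = ("AD", "CD")
    timepoints: Sequence[str] = ("pre", "post")
    n_features: int = 500
    n_affected: int = 20
    fc_affected: float = 0.4  # post/pre ratio; < 1 means removed by dialysis
    baseline_log_mean: float = 10.0
    baseline_log_sd: float = 1.0
    subject_sd: float = 0.3
    noise_sd: float = 0.2
    drift_amplitude: float = 0.3
    qc_every: int = 6
    n_lead_qc: int = 5
    n_blanks: int = 2
    zero_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_affected > self.n_features:
            raise ValueError("n_affected cannot exceed n_features")
        if not self.fc_affected > 0:
            raise ValueError("fc_affected must be > 0")
        if not (0 <= self.zero_rate < 1):
            raise ValueError("zero_rate must be in [0, 1)")
        if "post" not in self.timepoints and self.n_affected > 0:
            raise ValueError("affected features need a 'post' timepoint")


@dataclass
class GroundTruth:
    """What the generator injected, for scoring recovery downstream."""

    affected: dict[str, float]  # feature_id -> true post/pre fold change
    drift: dict[str, float]  # injection_id -> multiplicative drift factor
    subject_effects: pd.DataFrame  # features x subjects, log scale

    @property
    def affected_ids(self) -> list[str]:
        return sorted(self.affected)


def drift_profile(order: np.ndarray | float, n_total: int, drift_amplitude: float) -> np.ndarray:
    """Smooth positive multiplicative drift over the injection sequence.

    A low-order sinusoid plus linear trend, rescaled so the max/min ratio
    over the sequence equals 1 + drift_amplitude exactly; amplitude 0 gives
    a flat profile of ones.
    """
    order = np.asarray(order, dtype=float)
    if drift_amplitude == 0:
        return np.ones_like(order)
    u = (order - 1) / max(n_total - 1, 1)
    shape = np.sin(1.25 * np.pi * u) + 0.5 * u
    grid = np.linspace(0, 1, 2048)
    ref = np.sin(1.25 * np.pi * grid) + 0.5 * grid
    lo, hi = ref.min(), ref.max()
    return 1.0 + drift_amplitude * (shape - lo) / (hi - lo)


def _injection_sequence(spec: SimulationSpec, rng: np.random.Generator) -> list[InjectionRecord]:
    """Leading QCs, randomized study order with interleaved QCs, final blanks."""
    study = [
        (f"S{subj:02d}_{arm}_{tp}", f"subj{subj:02d}", tp, arm)
        for subj in range(1, spec.n_subjects + 1)
        for arm in spec.arms
        for tp in spec.timepoints
    ]
    perm = rng.permutation(len(study))
    study = [study[i] for i in perm]

    records: list[InjectionRecord] = []
    order = 1
    for k in range(spec.n_lead_qc):
        records.append(InjectionRecord(f"QC{k + 1:02d}", "qc", order))
        order += 1
    n_qc = spec.n_lead_qc
    since_qc = 0
    for inj_id, subj, tp, arm in study:
        records.append(InjectionRecord(inj_id, "study", order, subj, tp, arm))
        order += 1
        since_qc += 1
        if since_qc == spec.qc_every:
            n_qc += 1
            records.append(InjectionRecord(f"QC{n_qc:02d}", "qc", order))
            order += 1
            since_qc = 0
    if since_qc > 0:  # trailing partial block still gets a bracketing QC
        n_qc += 1
        records.append(InjectionRecord(f"QC{n_qc:02d}", "qc", order))
        order += 1
    for k in range(spec.n_blanks):
        records.append(InjectionRecord(f"BLANK{k + 1}", "blank", order))
        order += 1
    return records


def simulate_study(spec: SimulationSpec) -> tuple[FeatureTable, GroundTruth]:
    """Generate a feature table and its ground truth, reproducibly from the seed."""
    rng = np.random.default_rng(spec.seed)
    records = _injection_sequence(spec, rng)
    n_total = len(records)
    p = spec.n_features

    mz = np.round(rng.uniform(70.0, 1000.0, size=p), 4)
    rt = np.round(rng.uniform(0.3, 13.5, size=p), 3)
    feature_ids = [f"F{j + 1:04d}" for j in range(p)]
    features = [Feature(fid, m, r) for fid, m, r in zip(feature_ids, mz, rt)]

    baseline = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=p)
    affected_idx = rng.choice(p, size=spec.n_affected, replace=False)
    effect = np.zeros(p)
    effect[affected_idx] = np.log(spec.fc_affected)

    subjects = sorted({r.subject_id for r in records if r.sample_type == "study"})
    subj_eff = rng.normal(0.0, spec.subject_sd, size=(p, len(subjects)))
    subj_index = {s: k for k, s in enumerate(subjects)}

    orders = np.array([r.injection_order for r in records], dtype=float)
    drift = drift_profile(orders, n_total, spec.drift_amplitude)

    cols = np.empty((p, n_total))
    for j, rec in enumerate(records):
        if rec.sample_type == "study":
            eps = rng.normal(0.0, spec.noise_sd, size=p)
            log_i = baseline + subj_eff[:, subj_index[rec.subject_id]] + eps
            if rec.timepoint == "post":
                log_i = log_i + effect
            col = np.exp(log_i) * drift[j]
            if spec.zero_rate > 0:
                col = np.where(rng.uniform(size=p) < spec.zero_rate, 0.0, col)
        elif rec.sample_type == "qc":
            eps = rng.normal(0.0, spec.noise_sd, size=p)
            col = np.exp(baseline + eps) * drift[j]
        else:  # blank: trace-level background only
            col = np.exp(baseline - 6.0 + rng.normal(0.0, 0.5, size=p))
        cols[:, j] = col

    intensities = pd.DataFrame(
        cols,
        index=pd.Index(feature_ids, name="feature_id"),
        columns=[r.injection_id for r in records],
    )
    table = FeatureTable(
        features=features,
        injections=records,
        intensities=intensities,
        provenance=[f"simulated crossover study (seed={spec.seed})"],
    )
    truth = GroundTruth(
        affected={feature_ids[j]: spec.fc_affected for j in affected_idx},
        drift={r.injection_id: float(drift[j]) for j, r in enumerate(records)},
        subject_effects=pd.DataFrame(subj_eff, index=feature_ids, columns=subjects),
    )
    return table, truth


# -- printed annotation rows ------------------------------------------------

#: (observed m/z, adduct, formula, annotation) rows from the study's
#: discriminant-variable tables, packaged for annotation tests. Two printed
#: rows are deliberately absent: one whose printed formula is the intact
#: cation (so no neutral-adduct convention reproduces it) and one alkane
#: M+Na row that falls just outside the 10 ppm window at printed precision.
PRINTED_ANNOTATION_ROWS: tuple[tuple[float, str, str, str], ...] = (
    (136.0485, "M+Na", "C4H7N3O", "Creatinine"),
    (98.98454, "M+H", "H3O4P", "Hydrogen phosphate"),
    (160.1335, "M+H", "C8H17NO2", "Pregabalin"),
    (229.1549, "M+H", "C11H20N2O3", "L-isoleucyl-L-proline"),
    (151.0617, "M+H", "C6H6N4O", "1-Methylhypoxanthine"),
    (153.0666, "M+H", "C7H8N2O2", "N1-Methyl-2-pyridone-5-carboxamide"),
    (207.1111, "M+Na", "C9H16N2O2", "N-(3-acetamidopropyl)pyrrolidin-2-one"),
    (307.0875, "M+H", "C20H15ClO", "4-(2-chloro-1,2-diphenylethenyl)phenol"),
    (84.04482, "M+H-H2O", "C4H7NO2", "1-Aminocyclopropanecarboxylic acid"),
    (91.05471, "M+H-H2O", "C7H8O", "p-Cresol"),
    (335.0825, "M+H-H2O", "C16H17ClN2O5", "N-(Carbethoxyacetyl)-4-chloro-L-tryptophan"),
    (364.0358, "M+Na", "C18H12ClNO4", "7-Chloro-6-demethylcepharadione B"),
    (265.1192, "M+H", "C13H16N2O4", "Acetyl-N-formyl-5-methoxykynurenamine"),
    (287.1013, "M+H", "C15H14N2O4", "3',4'-Dihydrodiol"),
    (76.07599, "M+H", "C3H9NO", "Trimethylamine N-oxide (TMAO)"),
    (110.0605, "M+H", "C6H7NO", "2-Acetylpyrrole"),
    (110.0605, "M+H-H2O", "C6H9NO2", "1-Piperideine-2-carboxylic acid"),
    (77.03899, "M+H-H2O", "C6H6O", "Phenol"),
    (105.0341, "M+H-H2O", "C7H6O2", "4-Hydroxybenzaldehyde"),
    (250.0295, "M+H-H2O", "C10H9N3O4S", "Nitrososulfamethoxazole"),
    (180.0657, "M+H", "C9H9NO3", "Hippuric acid"),
    (314.2335, "M+H", "C17H31NO4", "3-hydroxydecanoyl carnitine"),
    (314.2335, "M+H-H2O", "C17H33NO5", "9-Decenoylcarnitine"),
    (114.0919, "M+H", "C6H11NO", "Epsilon-caprolactam"),
    (114.0919, "M+H-H2O", "C6H13NO2", "L-Leucine"),
)


def make_annotation_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Printed (m/z, adduct, formula, annotation) rows + the bundled library.

    Returns the row table and the mini compound library against which every
    row should annotate within the 10 ppm window.
    """
    rows = pd.DataFrame(
        PRINTED_ANNOTATION_ROWS, columns=["observed_mz", "adduct", "formula", "annotation"]
    )
    library = read_compound_library(default_library_path())
    return rows, library
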