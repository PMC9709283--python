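"""Core containers for paired LC-MS metabolomics tables.

A feature table holds one row per molecular feature — an LC-MS signal keyed
by accurate mass (m/z, Da) and retention time (min) — and one column per
injection (study sample, pooled QC, or blank). Intensities are relative,
non-negative, and may be zero (below detection).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd

TIMEPOINTS = ("pre", "mid", "post", "rebound")
ARMS = ("AD", "CD")
SAMPLE_TYPES = ("study", "qc", "blank")


class FeatureTableError(ValueError):
    """Structural problem in a feature table or its metadata."""


@dataclass(frozen=True)
class Feature:
    """A molecular feature keyed by accurate mass and retention time."""

    feature_id: str
    mz: float
    rt: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise FeatureTableError(f"feature {self.feature_id!r}: mz must be > 0, got {self.mz}")
        if self.rt < 0:
            raise FeatureTableError(f"feature {self.feature_id!r}: rt must be >= 0, got {self.rt}")


@dataclass(frozen=True)
class InjectionRecord:
    """One injection in the run sequence.

    Study injections must carry subject, timepoint and dialysate arm;
    QC pools and blanks leave those empty.
    """

    injection_id: str
    sample_type: str
    injection_order: int
    subject_id: Optional[str] = None
    timepoint: Optional[str] = None
    arm: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise FeatureTableError(
                f"injection {self.injection_id!r}: sample_type {self.sample_type!r} "
                f"not one of {SAMPLE_TYPES}"
            )
        if self.injection_order < 1:
            raise FeatureTableError(
                f"injection {self.injection_id!r}: injection_order must be a positive integer"
            )
        if self.timepoint is not None and self.timepoint not in TIMEPOINTS:
            raise FeatureTableError(
                f"injection {self.injection_id!r}: timepoint {self.timepoint!r} not in {TIMEPOINTS}"
            )
        if self.arm is not None and self.arm not in ARMS:
            raise FeatureTableError(
                f"injection {self.injection_id!r}: arm {self.arm!r} not in {ARMS}"
            )
        if self.sample_type == "study":
            missing = [
                name
                for name, val in (
                    ("subject_id", self.subject_id),
                    ("timepoint", self.timepoint),
                    ("arm", self.arm),
                )
                if val is None
            ]
            if missing:
                raise FeatureTableError(
                    f"study injection {self.injection_id!r} is missing {', '.join(missing)}"
                )


@dataclass
class FeatureTable:
    """Intensity matrix (features x injections) plus both axes of metadata.

    ``intensities`` is a DataFrame indexed by feature_id with one column per
    injection_id, kept in the order of ``features`` / ``injections``.
    ``provenance`` accumulates a free-text processing log, one entry per stage.
    """

    features: list[Feature]
    injections: list[InjectionRecord]
    intensities: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        fids = [f.feature_id for f in self.features]
        iids = [i.injection_id for i in self.injections]
        if len(set(fids)) != len(fids):
            dupes = sorted({x for x in fids if fids.count(x) > 1})
            raise FeatureTableError(f"duplicate feature ids: {dupes}")
        if len(set(iids)) != len(iids):
            dupes = sorted({x for x in iids if iids.count(x) > 1})
            raise FeatureTableError(f"duplicate injection ids: {dupes}")
        orders = [i.injection_order for i in self.injections]
        if len(set(orders)) != len(orders):
            raise FeatureTableError("injection_order values are not unique")
        if list(self.intensities.index) != fids or list(self.intensities.columns) != iids:
            raise FeatureTableError(
                "intensity matrix axes do not match the feature/injection lists "
                f"({self.intensities.shape} vs {len(fids)} features x {len(iids)} injections)"
            )
        vals = self.intensities.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise FeatureTableError("intensity matrix contains non-finite values")
        if (vals < 0).any():
            bad = self.intensities.index[(vals < 0).any(axis=1)][0]
            raise FeatureTableError(f"negative intensity in feature {bad!r}")

    # -- convenience views -------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_injections(self) -> int:
        return len(self.injections)

    def feature(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def injection_frame(self) -> pd.DataFrame:
        """Injection metadata as a DataFrame indexed by injection_id."""
        return pd.DataFrame(
            {
                "sample_type": [i.sample_type for i in self.injections],
                "injection_order": [i.injection_order for i in self.injections],
                "subject_id": [i.subject_id for i in self.injections],
                "timepoint": [i.timepoint for i in self.injections],
                "arm": [i.arm for i in self.injections],
            },
            index=pd.Index([i.injection_id for i in self.injections], name="injection_id"),
        )

    def feature_frame(self) -> pd.DataFrame:
        """Feature keys as a DataFrame indexed by feature_id."""
        return pd.DataFrame(
            {"mz": [f.mz for f in self.features], "rt": [f.rt for f in self.features]},
            index=pd.Index([f.feature_id for f in self.features], name="feature_id"),
        )

    def injection_ids(self, sample_type: Optional[str] = None) -> list[str]:
        return [
            i.injection_id
            for i in self.injections
            if sample_type is None or i.sample_type == sample_type
        ]

    def with_intensities(self, intensities: pd.DataFrame, note: str) -> "FeatureTable":
        """New table with a replaced matrix and a provenance entry appended."""
        return FeatureTable(
            features=list(self.features),
            injections=list(self.injections),
            intensities=intensities,
            provenance=[*self.provenance, note],
        )

    def select_features(self, feature_ids: Iterable[str], note: str) -> "FeatureTable":
        keep = set(feature_ids)
        feats = [f for f in self.features if f.feature_id in keep]
        return FeatureTable(
            features=feats,
            injections=list(self.injections),
            intensities=self.intensities.loc[[f.feature_id for f in feats]],
            provenance=[*self.provenance, note],
        )


Predicate = Callable[[InjectionRecord], bool]


@dataclass
class ComparisonSpec:
    """Two predicates over injections plus a pairing key (subject_id).

    ``group_a`` is the reference (e.g. pre-dialysis), ``group_b`` the
    contrast (e.g. post-dialysis); fold changes are reported as b over a.
    """

    name: str
    group_a: Predicate
    group_b: Predicate
    label_a: str = "a"
    label_b: str = "b"
    pairing_key: str = "subject_id"


def _tp_arm(timepoint: str, arm: Optional[str] = None) -> Predicate:
    def pred(rec: InjectionRecord) -> bool:
        if rec.sample_type != "study" or rec.timepoint != timepoint:
            return False
        return arm is None or rec.arm == arm

    return pred


def comparison_presets() -> dict[str, ComparisonSpec]:
    """The four study comparisons, addressable by name.

    Within-arm comparisons contrast pre- against post-dialysis samples;
    between-arm comparisons contrast acetate (AD) against citrate (CD)
    dialysate at a fixed timepoint.
    """
    return {
        "pre_vs_post_AD": ComparisonSpec(
            "pre_vs_post_AD", _tp_arm("pre", "AD"), _tp_arm("post", "AD"), "pre", "post"
        ),
        "pre_vs_post_CD": ComparisonSpec(
            "pre_vs_post_CD", _tp_arm("pre", "CD"), _tp_arm("post", "CD"), "pre", "post"
        ),
        "AD_vs_CD_post": ComparisonSpec(
            "AD_vs_CD_post", _tp_arm("post", "AD"), _tp_arm("post", "CD"), "AD", "CD"
        ),
        "AD_vs_CD_rebound": ComparisonSpec(
            "AD_vs_CD_rebound", _tp_arm("rebound", "AD"), _tp_arm("rebound", "CD"), "AD", "CD"
        ),
    }


@dataclass
class PairedData:
    """Per-subject paired intensity vectors for one comparison.

    ``a`` and ``b`` are feature x subject DataFrames sharing column order
    (sorted subject ids); ``dropped_subjects`` lists subjects lacking a
    complete pair, with the reason.
    """

    a: pd.DataFrame
    b: pd.DataFrame
    subjects: list[str]
    dropped_subjects: dict[str, str]

    @property
    def n_pairs(self) -> int:
        return len(self.subjects)


def subset_comparison(table: FeatureTable, spec: ComparisonSpec) -> PairedData:
    """Extract paired per-subject intensity vectors for one comparison.

    Each subject must contribute exactly one injection per group; subjects
    with extra injections in either group raise, subjects missing one side
    are dropped and recorded. Output subject order is sorted for determinism.
    """
    in_a = [i for i in table.injections if spec.group_a(i)]
    in_b = [i for i in table.injections if spec.group_b(i)]
    overlap = {i.injection_id for i in in_a} & {i.injection_id for i in in_b}
    if overlap:
        raise FeatureTableError(
            f"comparison {spec.name!r}: groups overlap on injections {sorted(overlap)}"
        )

    def by_subject(records: list[InjectionRecord], side: str) -> dict[str, str]:
        out: dict[str, str] = {}
        for rec in records:
            key = getattr(rec, spec.pairing_key)
            if key in out:
                raise FeatureTableError(
                    f"comparison {spec.name!r}: subject {key!r} has more than one "
                    f"injection in group {side}"
                )
            out[key] = rec.injection_id
        return out

    a_map = by_subject(in_a, spec.label_a)
    b_map = by_subject(in_b, spec.label_b)
    paired = sorted(set(a_map) & set(b_map))
    dropped = {s: f"missing {spec.label_b}" for s in sorted(set(a_map) - set(b_map))}
    dropped.update({s: f"missing {spec.label_a}" for s in sorted(set(b_map) - set(a_map))})
    if not paired:
        raise FeatureTableError(f"comparison {spec.name!r}: no complete pairs")

    a = table.intensities[[a_map[s] for s in paired]].copy()
    b = table.intensities[[b_map[s] for s in paired]].copy()
    a.columns = paired
    b.columns = paired
    return PairedData(a=a, b=b, subjects=paired, dropped_subjects=dropped)
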