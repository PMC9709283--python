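"""Delimited-text I/O for feature tables, metadata and compound libraries.

Dialect: features as rows, injections as columns. The first three columns of
a feature table are ``feature_id``, ``mz``, ``rt``; every further column is
an injection whose id must appear in the metadata sheet. Comma and tab
separators are sniffed from the header line.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import Feature, FeatureTable, FeatureTableError, InjectionRecord

_META_COLUMNS = ["injection_id", "sample_type", "injection_order", "subject_id", "timepoint", "arm"]


def _sniff_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_metadata(path: str | Path) -> list[InjectionRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    missing = [c for c in ("injection_id", "sample_type", "injection_order") if c not in df.columns]
    if missing:
        raise FeatureTableError(f"metadata {path.name}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            InjectionRecord(
                injection_id=str(row["injection_id"]),
                sample_type=str(row["sample_type"]),
                injection_order=int(row["injection_order"]),
                subject_id=_opt(row.get("subject_id")),
                timepoint=_opt(row.get("timepoint")),
                arm=_opt(row.get("arm")),
            )
        )
    return records


def read_feature_table(
    table_path: str | Path,
    metadata_path: str | Path,
    coerce_bad_cells: bool = False,
) -> FeatureTable:
    """Read and validate a feature table plus its injection metadata.

    Every intensity column must have a metadata row; unparseable numeric
    cells raise unless ``coerce_bad_cells`` turns them into zeros.
    """
    table_path = Path(table_path)
    df = pd.read_csv(table_path, sep=_sniff_sep(table_path), dtype=str)
    for col in ("feature_id", "mz", "rt"):
        if col not in df.columns:
            raise FeatureTableError(f"table {table_path.name}: missing column {col!r}")

    records = read_metadata(metadata_path)
    meta_ids = [r.injection_id for r in records]
    intensity_cols = [c for c in df.columns if c not in ("feature_id", "mz", "rt")]
    missing_meta = [c for c in intensity_cols if c not in meta_ids]
    if missing_meta:
        raise FeatureTableError(
            f"metadata is missing injections present in the table: {missing_meta}"
        )
    # keep only injections that actually have a column, in metadata order
    records = [r for r in records if r.injection_id in set(intensity_cols)]

    features = [
        Feature(feature_id=str(r.feature_id), mz=float(r.mz), rt=float(r.rt))
        for r in df.itertuples(index=False)
    ]

    raw = df[[r.injection_id for r in records]]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        if not coerce_bad_cells:
            rr, cc = np.argwhere(bad.to_numpy())[0]
            raise FeatureTableError(
                f"unparseable intensity at feature {df['feature_id'].iloc[rr]!r}, "
                f"injection {raw.columns[cc]!r}"
            )
        numeric = numeric.where(~bad, 0.0)
    numeric = numeric.fillna(0.0).astype(float)
    numeric.index = pd.Index([f.feature_id for f in features], name="feature_id")

    return FeatureTable(
        features=features,
        injections=records,
        intensities=numeric,
        provenance=[f"read {table_path.name} + {Path(metadata_path).name}"],
    )


def write_feature_table(table: FeatureTable, table_path: str | Path, metadata_path: str | Path,
                        sep: str = "\t") -> None:
    table_path, metadata_path = Path(table_path), Path(metadata_path)
    out = table.feature_frame().reset_index()
    out = pd.concat([out, table.intensities.reset_index(drop=True)], axis=1)
    out.to_csv(table_path, sep=sep, index=False)
    meta = table.injection_frame().reset_index()[_META_COLUMNS]
    meta.to_csv(metadata_path, sep=sep, index=False)


def read_compound_library(path: str | Path) -> pd.DataFrame:
    """Read a compound library (name, formula, compound_class, evidence flags).

    Optional boolean columns ``standard_confirmed`` and ``msms_match`` carry
    the identification evidence used for MSI confidence leveling.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    for col in ("name", "formula"):
        if col not in df.columns:
            raise FeatureTableError(f"library {path.name}: missing column {col!r}")
    if "compound_class" not in df.columns:
        df["compound_class"] = ""
    for flag in ("standard_confirmed", "msms_match"):
        if flag not in df.columns:
            df[flag] = False
        else:
            df[flag] = df[flag].fillna(False).astype(bool)
    return df


def default_library_path() -> Path:
    """Path of the bundled mini-library of plasma metabolites."""
    return Path(__file__).parent / "data" / "compound_library.tsv"
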