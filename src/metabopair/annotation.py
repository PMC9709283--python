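"""Formula masses, adduct m/z, ppm matching and MSI confidence levels.

Observed m/z values (positive electrospray) are matched against a compound
library by computing each compound's monoisotopic neutral mass from its
molecular formula, forming adduct ions (M+H, M+Na, M+H-H2O) and keeping
matches within a ppm tolerance. Matched features receive a Metabolomics
Standards Initiative confidence level: 1 when confirmed against a chemical
standard, 2 when the MS/MS spectrum matches a database record, 3 on an
accurate-mass-only match, 4 when nothing matches.
"""
from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

# IUPAC/CODATA monoisotopic masses (Da); immutable at runtime.
MONOISOTOPIC_MASS: Mapping[str, float] = MappingProxyType(
    {
        "C": 12.0,
        "H": 1.00782503207,
        "N": 14.0030740048,
        "O": 15.9949146196,
        "P": 30.97376163,
        "S": 31.97207100,
        "Na": 22.9897692809,
        "Cl": 34.96885268,
        "F": 18.99840322,
        "K": 38.96370668,
        "Se": 79.9165213,
        "I": 126.904473,
        "Br": 78.9183371,
    }
)

PROTON_MASS = 1.007276466879  # Da; H atom minus one electron
ELECTRON_MASS = 0.000548579909  # Da
WATER_MASS = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]


class FormulaError(ValueError):
    """Molecular formula cannot be parsed."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element-count map parsed from a Hill-style formula string."""

    counts: Mapping[str, int]
    source: str

    def mass(self) -> float:
        return monoisotopic_mass(self)


@dataclass(frozen=True)
class AdductSpec:
    """Positive-mode adduct: observed m/z = (M + shift) / |charge|.

    Shifts follow the charged-species convention (proton mass, electron
    corrected), not the neutral hydrogen atom mass.
    """

    name: str
    shift: float
    charge: int = 1


ADDUCTS: Mapping[str, AdductSpec] = MappingProxyType(
    {
        "M+H": AdductSpec("M+H", PROTON_MASS),
        "M+Na": AdductSpec("M+Na", MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS),
        "M+H-H2O": AdductSpec("M+H-H2O", PROTON_MASS - WATER_MASS),
    }
)

_SUBSCRIPT_DIGITS = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse ``"C4H7N3O"`` (also tolerating ``"C_4_H_7_N_3_O"`` markup).

    Bare element symbols count 1; unknown symbols and explicit zero counts
    are errors that name the offending position.
    """
    source = text
    cleaned = unicodedata.normalize("NFKC", text).translate(_SUBSCRIPT_DIGITS)
    cleaned = cleaned.replace("_", "").replace(" ", "")
    if not cleaned:
        raise FormulaError(f"empty formula {text!r}")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN.match(cleaned, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        symbol, digits = m.groups()
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {symbol!r} in formula {text!r} at position {pos}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {symbol!r} in formula {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return MolecularFormula(counts=MappingProxyType(counts), source=source)


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Monoisotopic neutral mass (Da) of a formula; empty map -> 0."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts.items())


def adduct_mz(neutral_mass: float, adduct: AdductSpec | str) -> float:
    """Theoretical m/z of an adduct ion of a neutral of the given mass."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    mz = (neutral_mass + adduct.shift) / abs(adduct.charge)
    if mz <= 0:
        raise ValueError(
            f"adduct {adduct.name} of mass {neutral_mass} Da gives non-positive m/z"
        )
    return mz


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class AnnotationHit:
    compound: str
    formula: str
    compound_class: str
    adduct: str
    theoretical_mz: float
    observed_mz: float
    ppm_error: float
    msi_level: int


def match_library(
    observed_mz: float,
    library: pd.DataFrame,
    adducts: Sequence[str] = ("M+H", "M+Na", "M+H-H2O"),
    tolerance_ppm: float = 10.0,
) -> list[AnnotationHit]:
    """All (compound, adduct) pairs within the ppm window of an observed m/z.

    The library needs ``name`` and ``formula`` columns (see
    :func:`metabopair.io.read_compound_library`). Hits are sorted by
    |ppm error| then compound name; every candidate is reported, no
    winner-takes-all. Evidence flags in the library set the MSI level.
    """
    hits: list[AnnotationHit] = []
    for row in library.itertuples(index=False):
        try:
            neutral = monoisotopic_mass(str(row.formula))
        except FormulaError:
            continue
        for name in adducts:
            spec = ADDUCTS[name]
            if neutral + spec.shift <= 0:
                continue
            theo = adduct_mz(neutral, spec)
            err = ppm_error(observed_mz, theo)
            if abs(err) <= tolerance_ppm:
                level = assign_msi_level(
                    True,
                    standard_confirmed=bool(getattr(row, "standard_confirmed", False)),
                    msms_match=bool(getattr(row, "msms_match", False)),
                )
                hits.append(
                    AnnotationHit(
                        compound=str(row.name),
                        formula=str(row.formula),
                        compound_class=str(getattr(row, "compound_class", "")),
                        adduct=name,
                        theoretical_mz=theo,
                        observed_mz=observed_mz,
                        ppm_error=err,
                        msi_level=level,
                    )
                )
    hits.sort(key=lambda h: (abs(h.ppm_error), h.compound))
    return hits


def assign_msi_level(
    has_mass_hit: bool, standard_confirmed: bool = False, msms_match: bool = False
) -> int:
    """MSI confidence level from the available identification evidence."""
    if not has_mass_hit:
        return 4
    if standard_confirmed:
        return 1
    if msms_match:
        return 2
    return 3


def annotate_features(
    features: Iterable[tuple[str, float]],
    library: pd.DataFrame,
    adducts: Sequence[str] = ("M+H", "M+Na", "M+H-H2O"),
    tolerance_ppm: float = 10.0,
) -> pd.DataFrame:
    """Annotate (feature_id, observed m/z) pairs against a library.

    Returns one row per hit, plus a level-4 "Unknown" row for features with
    no hit, in the shape of the study's annotation tables.
    """
    rows = []
    for feature_id, mz in features:
        hits = match_library(mz, library, adducts=adducts, tolerance_ppm=tolerance_ppm)
        if not hits:
            rows.append(
                dict(
                    feature_id=feature_id, observed_mz=mz, compound="Unknown", formula="",
                    compound_class="", adduct="", theoretical_mz=float("nan"),
                    ppm_error=float("nan"), msi_level=4,
                )
            )
        for h in hits:
            rows.append(
                dict(
                    feature_id=feature_id, observed_mz=mz, compound=h.compound,
                    formula=h.formula, compound_class=h.compound_class, adduct=h.adduct,
                    theoretical_mz=h.theoretical_mz, ppm_error=h.ppm_error,
                    msi_level=h.msi_level,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "observed_mz", "compound", "formula", "compound_class",
            "adduct", "theoretical_mz", "ppm_error", "msi_level",
        ],
    )
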