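"""Subject tables and log-feature matrices.

A cohort is a list of :class:`SubjectRecord`, one per participant, each
carrying a class label (breast-cancer case vs healthy control) and the
measured concentrations of four estrogen-quinone protein adducts:
hemoglobin (Hb) and albumin (Alb) adducts of estradiol-3,4-quinone and
estradiol-2,3-quinone.  Cohorts round-trip through a plain CSV schema
(XLSX is accepted read-only under the same header contract) and are turned
into the natural-log feature matrices the risk model consumes.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Adduct",
    "FULL_PANEL",
    "AdductSubset",
    "SubjectRecord",
    "FeatureMatrix",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "build_features",
]

CASE = "case"
CONTROL = "control"

#: Aliases accepted (case-insensitively) for the two group labels.
_GROUP_ALIASES = {
    "case": CASE,
    "bcp": CASE,
    "cancer": CASE,
    "patient": CASE,
    "control": CONTROL,
    "hc": CONTROL,
    "healthy": CONTROL,
}


class Adduct(str, Enum):
    """The four quantified estrogen-quinone protein adducts.

    The value of each member is its column name in the cohort CSV schema.
    """

    HB_34Q = "hb_e2_34q"
    HB_23Q = "hb_e2_23q"
    ALB_34Q = "alb_e2_34q"
    ALB_23Q = "alb_e2_23q"


#: Canonical feature order: Hb 3,4-Q, Hb 2,3-Q, Alb 3,4-Q, Alb 2,3-Q.
FULL_PANEL: tuple[Adduct, ...] = (
    Adduct.HB_34Q,
    Adduct.HB_23Q,
    Adduct.ALB_34Q,
    Adduct.ALB_23Q,
)


@dataclass(frozen=True)
class AdductSubset:
    """An ordered, duplicate-free selection of adducts used as model inputs."""

    included: tuple[Adduct, ...]

    def __post_init__(self) -> None:
        if not self.included:
            raise ValueError("adduct subset must be non-empty")
        if len(set(self.included)) != len(self.included):
            raise ValueError("adduct subset contains duplicates")
        object.__setattr__(self, "included", tuple(Adduct(a) for a in self.included))

    def __len__(self) -> int:
        return len(self.included)

    def __iter__(self):
        return iter(self.included)

    def labels(self) -> list[str]:
        return [a.value for a in self.included]


#: All four adducts, in canonical order.
FULL_SUBSET = AdductSubset(FULL_PANEL)


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: identifier, group label, and the four concentrations.

    Concentrations are strictly positive reals (the model works on their
    natural logarithms); ``group`` is ``"case"`` or ``"control"``.
    """

    subject_id: str
    group: str
    conc_hb_34q: float
    conc_hb_23q: float
    conc_alb_34q: float
    conc_alb_23q: float

    def __post_init__(self) -> None:
        if self.group not in (CASE, CONTROL):
            raise ValueError(f"group must be 'case' or 'control', got {self.group!r}")
        for adduct in FULL_PANEL:
            value = self.concentration(adduct)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValueError(
                    f"subject {self.subject_id!r}: concentration {adduct.value} "
                    f"must be a finite positive number, got {value!r}"
                )

    _FIELD_BY_ADDUCT = {
        Adduct.HB_34Q: "conc_hb_34q",
        Adduct.HB_23Q: "conc_hb_23q",
        Adduct.ALB_34Q: "conc_alb_34q",
        Adduct.ALB_23Q: "conc_alb_23q",
    }

    def concentration(self, adduct: Adduct) -> float:
        return getattr(self, self._FIELD_BY_ADDUCT[Adduct(adduct)])

    @property
    def is_case(self) -> bool:
        return self.group == CASE


@dataclass(frozen=True)
class FeatureMatrix:
    """Log-concentration design matrix plus binary labels.

    ``x[i, j]`` is the natural log of subject ``i``'s concentration of the
    ``j``-th adduct in ``adducts``; ``y[i]`` is 1 for cases, 0 for controls.
    """

    x: np.ndarray
    y: np.ndarray
    subject_ids: tuple[str, ...]
    adducts: AdductSubset

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 2 or x.shape[0] != y.shape[0]:
            raise ValueError("x must be 2-D with one row per label")
        if x.shape[1] != len(self.adducts):
            raise ValueError("column count must match the adduct subset")
        if not np.all(np.isfinite(x)):
            raise ValueError("feature matrix contains non-finite entries")
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("labels must be 0/1")

    @property
    def n_subjects(self) -> int:
        return self.x.shape[0]

    @property
    def n_features(self) -> int:
        return self.x.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())


class SchemaError(ValueError):
    """A cohort table is missing required columns."""


_REQUIRED_COLUMNS = ("subject_id", "group") + tuple(a.value for a in FULL_PANEL)


def _normalise_group(raw: object, row: int) -> str:
    key = str(raw).strip().lower()
    if key not in _GROUP_ALIASES:
        raise ValueError(f"row {row}: unrecognised group label {raw!r}")
    return _GROUP_ALIASES[key]


def read_cohort(path: str | Path, dialect: str | None = None) -> list[SubjectRecord]:
    """Read a cohort table from CSV or XLSX.

    Parameters
    ----------
    path : path-like
        File with a header naming ``subject_id``, ``group`` and the four
        adduct columns (see :class:`Adduct` values).  Extra columns are
        ignored.
    dialect : {"delimited", "spreadsheet"}, optional
        Forced format; by default inferred from the suffix (``.xlsx`` /
        ``.xls`` is spreadsheet, anything else delimited).

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValueError
        If a concentration is non-numeric or not strictly positive; the
        message names the offending row and column.
    """
    path = Path(path)
    if dialect is None:
        dialect = "spreadsheet" if path.suffix.lower() in (".xlsx", ".xls") else "delimited"
    if dialect == "spreadsheet":
        frame = pd.read_excel(path)
    elif dialect == "delimited":
        frame = pd.read_csv(path, float_precision="round_trip")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    frame.columns = [str(c).strip().lower() for c in frame.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    records: list[SubjectRecord] = []
    for row, entry in enumerate(frame.itertuples(index=False), start=1):
        values = dict(zip(frame.columns, entry))
        concentrations = {}
        for adduct in FULL_PANEL:
            raw = values[adduct.value]
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {row}, column {adduct.value}: non-numeric value {raw!r}"
                ) from None
            if not math.isfinite(value) or value <= 0:
                raise ValueError(
                    f"row {row}, column {adduct.value}: concentration must be "
                    f"> 0, got {raw!r}"
                )
            concentrations[adduct] = value
        records.append(
            SubjectRecord(
                subject_id=str(values["subject_id"]),
                group=_normalise_group(values["group"], row),
                conc_hb_34q=concentrations[Adduct.HB_34Q],
                conc_hb_23q=concentrations[Adduct.HB_23Q],
                conc_alb_34q=concentrations[Adduct.ALB_34Q],
                conc_alb_23q=concentrations[Adduct.ALB_23Q],
            )
        )
    return records


def write_cohort(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write a cohort as comma-delimited text with full-precision floats.

    Concentrations are rendered with ``repr`` so that a read-back cohort is
    bit-identical to the one written.
    """
    if not records:
        raise ValueError("refusing to write an empty cohort")
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_REQUIRED_COLUMNS)
        for record in records:
            writer.writerow(
                [record.subject_id, record.group]
                + [repr(record.concentration(a)) for a in FULL_PANEL]
            )


def build_features(
    records: Sequence[SubjectRecord],
    subset: AdductSubset | Iterable[Adduct] = FULL_SUBSET,
) -> FeatureMatrix:
    """Assemble the natural-log feature matrix for a subset of adducts.

    Column order always follows ``subset``, independent of how the cohort
    file was laid out; labels are 1 for cases and 0 for controls.
    """
    if not records:
        raise ValueError("cannot build features from an empty cohort")
    if not isinstance(subset, AdductSubset):
        subset = AdductSubset(tuple(subset))
    x = np.array(
        [[math.log(r.concentration(a)) for a in subset] for r in records],
        dtype=float,
    )
    y = np.array([1.0 if r.is_case else 0.0 for r in records])
    return FeatureMatrix(
        x=x, y=y, subject_ids=tuple(r.subject_id for r in records), adducts=subset
    )
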