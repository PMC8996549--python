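"""Record and stratum data model.

The pipeline operates on tabular laboratory records: one row per measurement
of one analyte on one subject at one collection date.  In-memory the canonical
container is a :class:`pandas.DataFrame` wrapped by :class:`Dataset`; the
columns are fixed so every stage can rely on them.

Age/sex strata follow the half-open convention ``age_lo <= age < age_hi`` in
decimal years (so "1 to <6 years" is ``[1, 6)``).  A *partition scheme* is a
list of disjoint strata per analyte that together cover the study age range.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of a record table
COLUMNS = ["subject_id", "date", "age", "sex", "analyte", "value", "units", "source"]

#: default units per analyte
DEFAULT_UNITS = {"creatinine": "umol/L", "urea": "mmol/L", "uric_acid": "umol/L"}

_SEX_ALIASES = {
    "m": "male", "male": "male", "boy": "male", "b": "male",
    "f": "female", "female": "female", "girl": "female", "g": "female",
}


def normalize_sex(value: str) -> str:
    """Map case-insensitive sex spellings ({M, F, male, female, ...}) to
    the internal ``male``/``female`` encoding."""
    try:
        return _SEX_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise ValueError(f"unrecognized sex value: {value!r}") from None


@dataclass(frozen=True)
class AnalyteRecord:
    """One laboratory measurement with subject/age/sex/date context."""

    subject_id: str
    date: datetime.date
    age: float            # decimal years
    sex: str              # 'male' | 'female'
    analyte: str
    value: float
    units: str = ""
    source: str = "lis"   # 'direct' | 'lis'

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("record value must be finite")
        if self.age < 0:
            raise ValueError("age must be non-negative")
        object.__setattr__(self, "sex", normalize_sex(self.sex))


@dataclass(frozen=True)
class Stratum:
    """Half-open age band (optionally sex-specific) for one analyte."""

    analyte: str
    age_lo: float
    age_hi: float
    sex: str = "any"     # 'any' | 'male' | 'female'
    label: str = ""

    def __post_init__(self) -> None:
        if not self.age_lo < self.age_hi:
            raise ValueError("stratum requires age_lo < age_hi")
        if self.sex not in ("any", "male", "female"):
            object.__setattr__(self, "sex", normalize_sex(self.sex))
        if not self.label:
            sex_tag = "" if self.sex == "any" else f" {self.sex}"
            object.__setattr__(
                self, "label",
                f"{self.analyte} {self.age_lo:g} to <{self.age_hi:g} years{sex_tag}",
            )

    def contains(self, age: float, sex: str, analyte: Optional[str] = None) -> bool:
        if analyte is not None and analyte != self.analyte:
            return False
        if self.sex != "any" and normalize_sex(sex) != self.sex:
            return False
        return self.age_lo <= age < self.age_hi


def default_scheme() -> list[Stratum]:
    """Published creatinine/urea partition: creatinine in three age bands with
    a sex split in the adolescent band; urea in a single 1 to <17 y stratum."""
    return [
        Stratum("creatinine", 1, 6, "any", "creatinine 1 to <6 years"),
        Stratum("creatinine", 6, 12, "any", "creatinine 6 to <12 years"),
        Stratum("creatinine", 12, 17, "male", "creatinine 12 to <17 years boys"),
        Stratum("creatinine", 12, 17, "female", "creatinine 12 to <17 years girls"),
        Stratum("urea", 1, 17, "any", "urea 1 to <17 years"),
    ]


def cleaning_scheme() -> list[Stratum]:
    """Strata used during outlier detection: the reporting scheme plus a
    single uric-acid stratum (uric acid is screened for the radical
    multi-analyte exclusion even though no RI is reported for it)."""
    return default_scheme() + [
        Stratum("uric_acid", 1, 17, "any", "uric_acid 1 to <17 years"),
    ]


def _sexes_overlap(a: str, b: str) -> bool:
    return a == "any" or b == "any" or a == b


def validate_scheme(scheme: Sequence[Stratum]) -> None:
    """Raise if any two strata of the same analyte overlap (age and sex)."""
    for i, s in enumerate(scheme):
        for t in scheme[i + 1:]:
            if s.analyte != t.analyte or not _sexes_overlap(s.sex, t.sex):
                continue
            if s.age_lo < t.age_hi and t.age_lo < s.age_hi:
                raise ValueError(f"overlapping strata: {s.label!r} and {t.label!r}")


def assign_stratum(record: AnalyteRecord, scheme: Sequence[Stratum]) -> Optional[Stratum]:
    """The unique stratum containing the record, or None.

    Uniqueness is guaranteed by scheme validation (overlap is a hard error).
    """
    validate_scheme(scheme)
    for s in scheme:
        if s.contains(record.age, record.sex, record.analyte):
            return s
    return None


def assign_strata(df: pd.DataFrame, scheme: Sequence[Stratum]) -> pd.Series:
    """Vectorized stratum labelling of a record table.

    Returns a Series of stratum labels aligned with ``df``; rows falling in no
    stratum get ``None``.
    """
    validate_scheme(scheme)
    labels = pd.Series([None] * len(df), index=df.index, dtype=object)
    for s in scheme:
        mask = (
            (df["analyte"] == s.analyte)
            & (df["age"] >= s.age_lo)
            & (df["age"] < s.age_hi)
        )
        if s.sex != "any":
            mask &= df["sex"] == s.sex
        labels[mask] = s.label
    return labels


class Dataset:
    """Ordered collection of analyte records backed by a DataFrame.

    Enforces the table schema and the uniqueness invariant on
    ``(subject_id, analyte, date, value)`` (exact duplicates are dropped with
    a logged count).
    """

    def __init__(self, df: pd.DataFrame, provenance: str = ""):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"record table missing columns: {missing}")
        df = df.loc[:, COLUMNS].reset_index(drop=True)
        n0 = len(df)
        df = df.drop_duplicates(subset=["subject_id", "analyte", "date", "value"])
        if len(df) < n0:
            logger.info("dropped %d exact duplicate records", n0 - len(df))
        if len(df) and not np.isfinite(df["value"].to_numpy(float)).all():
            raise ValueError("record values must be finite")
        self._df = df.reset_index(drop=True)
        self.provenance = provenance

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def replace(self, df: pd.DataFrame) -> "Dataset":
        """New Dataset with the same provenance and a new table."""
        return Dataset(df, provenance=self.provenance)

    @classmethod
    def from_records(cls, records: Iterable[AnalyteRecord], provenance: str = "") -> "Dataset":
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows, columns=COLUMNS)
        return cls(df, provenance=provenance)

    def to_records(self) -> list[AnalyteRecord]:
        return [
            AnalyteRecord(
                subject_id=str(r.subject_id), date=r.date, age=float(r.age),
                sex=str(r.sex), analyte=str(r.analyte), value=float(r.value),
                units=str(r.units), source=str(r.source),
            )
            for r in self._df.itertuples(index=False)
        ]

    def mask_for(self, stratum: Stratum, match_analyte: bool = True) -> pd.Series:
        """Boolean row mask for records inside a stratum (age/sex and, by
        default, analyte)."""
        df = self._df
        mask = (df["age"] >= stratum.age_lo) & (df["age"] < stratum.age_hi)
        if match_analyte:
            mask &= df["analyte"] == stratum.analyte
        if stratum.sex != "any":
            mask &= df["sex"] == stratum.sex
        return mask

    def values_for(self, stratum: Stratum) -> np.ndarray:
        """Values of the stratum's analyte for records inside the stratum."""
        return self._df.loc[self.mask_for(stratum), "value"].to_numpy(float)

    def subset(self, mask: pd.Series | np.ndarray) -> "Dataset":
        return self.replace(self._df.loc[mask])
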