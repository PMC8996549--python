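"""CSV / YAML input-output.

Record tables travel as plain UTF-8 CSV with header columns
``subject_id, date, age_years, sex, analyte, value, units, source``
(ISO-8601 dates, dot decimal separator).  A *schema* mapping lets files with
other header names be adapted at read time.  Partition schemes and
transference maps are read from YAML/JSON lists of mappings.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .data_model import COLUMNS, Dataset, Stratum, normalize_sex
from .transference import TransferenceMap

logger = logging.getLogger(__name__)

#: on-disk header -> internal column
_DEFAULT_SCHEMA = {
    "subject_id": "subject_id",
    "date": "date",
    "age_years": "age",
    "sex": "sex",
    "analyte": "analyte",
    "value": "value",
    "units": "units",
    "source": "source",
}

_OPTIONAL = {"units": "", "source": "lis"}


def read_records(path: str | Path, schema: Optional[Mapping[str, str]] = None,
                 provenance: str = "") -> Dataset:
    """Read a record CSV into a :class:`Dataset`.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping ``{file column -> internal column}`` overriding the
        default header names; internal columns are
        ``subject_id, date, age, sex, analyte, value, units, source``.

    Rows whose value, age or date fail to parse (or are blank) are skipped
    with a logged warning count.  A missing *required* column is a hard error
    naming the column.
    """
    schema = dict(schema) if schema else dict(_DEFAULT_SCHEMA)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {src: dst for src, dst in schema.items() if src in raw.columns}
    df = raw.rename(columns=rename)
    for col in COLUMNS:
        if col in _OPTIONAL:
            if col not in df.columns:
                df[col] = _OPTIONAL[col]
            continue
        if col not in df.columns:
            raise ValueError(f"required column missing from {path}: {col!r}")

    n0 = len(df)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601", errors="coerce").dt.date
    try:
        df["sex"] = df["sex"].map(normalize_sex)
    except ValueError:
        ok = df["sex"].str.strip().str.lower().isin(
            {"m", "f", "male", "female", "boy", "girl", "b", "g"})
        df = df.loc[ok]
        df["sex"] = df["sex"].map(normalize_sex)
    df = df.dropna(subset=["value", "age", "date"])
    df = df.loc[df["age"] >= 0]
    dropped = n0 - len(df)
    if dropped:
        logger.warning("read_records(%s): skipped %d malformed row(s)", path, dropped)
    return Dataset(df, provenance=provenance or f"read from {path}")


def write_records(ds: Dataset, path: str | Path) -> None:
    """Write a Dataset back to CSV (inverse of :func:`read_records`)."""
    df = ds.df.rename(columns={"age": "age_years"})
    df.to_csv(path, index=False)


# -- configuration objects -------------------------------------------------

def load_scheme(path: str | Path) -> list[Stratum]:
    """Read a partition scheme from a YAML/JSON list of
    ``{analyte, age_lo, age_hi, sex, label}`` mappings."""
    with open(path) as fh:
        items = yaml.safe_load(fh)
    return [
        Stratum(
            analyte=d["analyte"], age_lo=float(d["age_lo"]), age_hi=float(d["age_hi"]),
            sex=d.get("sex", "any"), label=d.get("label", ""),
        )
        for d in items
    ]


def save_scheme(scheme: Sequence[Stratum], path: str | Path) -> None:
    items = [
        {"analyte": s.analyte, "age_lo": s.age_lo, "age_hi": s.age_hi,
         "sex": s.sex, "label": s.label}
        for s in scheme
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(items, fh, sort_keys=False)


def load_maps(path: str | Path) -> list[TransferenceMap]:
    """Read transference maps from a YAML/JSON list of
    ``{analyte, source, target, slope, intercept}`` mappings."""
    with open(path) as fh:
        items = yaml.safe_load(fh)
    return [
        TransferenceMap(
            analyte=d["analyte"], source=d["source"], target=d["target"],
            slope=float(d["slope"]), intercept=float(d["intercept"]),
        )
        for d in items
    ]


def save_maps(maps: Sequence[TransferenceMap], path: str | Path) -> None:
    items = [
        {"analyte": m.analyte, "source": m.source, "target": m.target,
         "slope": m.slope, "intercept": m.intercept}
        for m in maps
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(items, fh, sort_keys=False)
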