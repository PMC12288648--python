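"""Readers for eICU-style delimited table extracts."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .concepts import TABLES, RawRecord
from .reference import Encounter

__all__ = ["read_tables", "read_patient_table", "CorruptTableError"]

logger = logging.getLogger(__name__)


class CorruptTableError(RuntimeError):
    """Malformed-row fraction exceeded the tolerated threshold."""


def _read_csv(path: Path) -> pd.DataFrame:
    # strings kept verbatim: no NA coercion, no dtype inference
    return pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")


def read_tables(
    table_dir: str | Path,
    encounter_col: str = "patientunitstayid",
    max_bad_fraction: float = 0.05,
) -> tuple[list[RawRecord], list[Encounter]]:
    """Read the nine source tables (and patient.csv) from *table_dir*.

    Missing table files are skipped with a warning. Rows whose offset
    does not parse as an integer are counted, logged and skipped; if the
    bad fraction of any file exceeds *max_bad_fraction* the read aborts
    with :class:`CorruptTableError`. Column names follow the eICU
    convention; *encounter_col* overrides the encounter-id column for
    other dialects.
    """
    table_dir = Path(table_dir)
    records: list[RawRecord] = []
    for name, spec in TABLES.items():
        path = table_dir / f"{spec.file_stem}.csv"
        if not path.exists():
            logger.warning("table file %s missing, skipped", path)
            continue
        df = _read_csv(path)
        required = [encounter_col, spec.offset_col, *spec.fields]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise CorruptTableError(f"{path}: missing column(s) {missing}")
        offsets = pd.to_numeric(df[spec.offset_col], errors="coerce")
        bad = offsets.isna()
        if bad.any():
            logger.warning("%s: %d row(s) with unparseable offsets skipped", path, int(bad.sum()))
            if len(df) and bad.sum() / len(df) > max_bad_fraction:
                raise CorruptTableError(
                    f"{path}: {int(bad.sum())}/{len(df)} rows malformed "
                    f"(> {max_bad_fraction:.0%} threshold)"
                )
        good = df.loc[~bad]
        offs = offsets.loc[~bad].astype(int)
        for (_, row), off in zip(good.iterrows(), offs):
            records.append(
                RawRecord.make(
                    str(row[encounter_col]),
                    name,
                    int(off),
                    **{c: row[c] for c in spec.fields},
                )
            )
    encounters = read_patient_table(table_dir / "patient.csv", encounter_col)
    return records, encounters


def read_patient_table(path: str | Path, encounter_col: str = "patientunitstayid") -> list[Encounter]:
    path = Path(path)
    if not path.exists():
        logger.warning("patient table %s missing; no encounter metadata", path)
        return []
    df = _read_csv(path)
    out = []
    for _, row in df.iterrows():
        try:
            order = int(row["unitvisitnumber"])
        except (KeyError, ValueError):
            logger.warning("patient row for %s: bad unitvisitnumber, skipped", row.get(encounter_col))
            continue
        out.append(Encounter(str(row[encounter_col]), str(row["uniquepid"]), str(row["age"]), order))
    return out
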