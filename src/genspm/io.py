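"""Readers and writers for the long-format delimited exchange files.

The cohort format is tab-separated with one row per person-exam:
``id, sex, genotype {carrier, noncarrier, unknown}, exam_age, value,
event_age, event {1 = death, 0 = censored}``.  A raw-followup variant
(schema="raw") carries death ages without the censoring rule applied; on
load, any death more than ``censor_lag`` years after the last measurement is
converted to censoring at last measurement + ``censor_lag``, mirroring the
convention of biennial-exam studies.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .records import IndividualRecord, genotype_code, genotype_label

__all__ = ["COLUMNS", "read_cohort", "write_cohort", "records_to_frame"]

log = logging.getLogger("genspm")

COLUMNS = ["id", "sex", "genotype", "exam_age", "value", "event_age", "event"]


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for rec in records:
        for age, val in zip(rec.ages, rec.values):
            rows.append(
                {
                    "id": rec.id,
                    "sex": rec.sex,
                    "genotype": genotype_label(rec.genotype),
                    "exam_age": float(age),
                    "value": float(val),
                    "event_age": float(rec.event_age),
                    "event": int(rec.event),
                }
            )
    return pd.DataFrame(rows, columns=COLUMNS)


def write_cohort(records_or_frame, path) -> None:
    df = (
        records_or_frame
        if isinstance(records_or_frame, pd.DataFrame)
        else records_to_frame(records_or_frame)
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort(path, schema: str = "standard", censor_lag: float = 2.0) -> list:
    """Read and validate a cohort file into IndividualRecord objects.

    Rows with missing mandatory fields are rejected with line-numbered
    diagnostics; records violating per-record invariants are dropped with a
    logged count.  ``schema="raw"`` applies the censoring rule to deaths far
    from the last measurement instead of rejecting them.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: empty dataset")
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    bad = df[COLUMNS].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header and 1-based lines
        raise ValueError(
            f"{path}: missing mandatory fields on line(s) {lines[:10]}"
            + ("..." if len(lines) > 10 else "")
        )

    records, dropped = [], 0
    for rec_id, sub in df.groupby("id", sort=False):
        sub = sub.sort_values("exam_age")
        event = bool(int(sub["event"].iloc[0]))
        event_age = float(sub["event_age"].iloc[0])
        last_age = float(sub["exam_age"].iloc[-1])
        if schema == "raw" and event and event_age - last_age > censor_lag + 1e-9:
            event, event_age = False, last_age + censor_lag
        rec = IndividualRecord(
            id=str(rec_id),
            sex=str(sub["sex"].iloc[0]),
            genotype=genotype_code(str(sub["genotype"].iloc[0])),
            ages=sub["exam_age"].to_numpy(dtype=float),
            values=sub["value"].to_numpy(dtype=float),
            event_age=event_age,
            event=event,
        )
        try:
            rec.validate(censor_lag=censor_lag)
        except ValueError as e:
            dropped += 1
            log.warning("dropping invalid record: %s", e)
            continue
        records.append(rec)
    if dropped:
        log.warning("%d invalid record(s) dropped from %s", dropped, path)
    if not records:
        raise ValueError(f"{path}: no valid records")
    return records
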