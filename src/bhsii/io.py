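"""Reading and writing response sheets and cohort tables.

Response sheets travel as long-format UTF-8 CSV with the header
``subject_id,timepoint,item_id,value`` — one row per answered item, an
empty value field meaning "not answered".  The timepoint vocabulary is
closed: T0/T1/T3/T6 for surgical follow-up, test/retest for the control
group.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .errors import ValidationError
from .instrument import InstrumentDefinition, ResponseSheet, load_default_instrument

RESPONSES_HEADER = ["subject_id", "timepoint", "item_id", "value"]
TIMEPOINTS = ("T0", "T1", "T3", "T6", "test", "retest")


class ResponseFileError(ValidationError):
    """Malformed rows in a response CSV, with line numbers."""

    def __init__(self, path, row_errors: List[Tuple[int, str]]):
        self.path = str(path)
        self.row_errors = row_errors
        lines = "; ".join(f"line {n}: {msg}" for n, msg in row_errors[:10])
        more = "" if len(row_errors) <= 10 else f" (+{len(row_errors) - 10} more)"
        super().__init__(f"{path}: {lines}{more}")


def read_responses(
    path,
    instrument: Optional[InstrumentDefinition] = None,
) -> List[ResponseSheet]:
    """Read and validate a long-format response CSV into sheets.

    All malformed rows (unknown item, non-integer or out-of-range value,
    duplicate (subject, timepoint, item), unknown timepoint) are
    collected and reported together in a single :class:`ResponseFileError`
    carrying line numbers.
    """
    if instrument is None:
        instrument = load_default_instrument()
    item_map = instrument.item_map
    sheets: Dict[Tuple[str, str], ResponseSheet] = {}
    errors: List[Tuple[int, str]] = []

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != RESPONSES_HEADER:
            raise ValidationError(
                f"{path}: expected header {','.join(RESPONSES_HEADER)!r}, "
                f"got {','.join(header or [])!r}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) != 4:
                errors.append((line_no, f"expected 4 fields, got {len(row)}"))
                continue
            subject_id, timepoint, item_id, raw_value = (f.strip() for f in row)
            if timepoint not in TIMEPOINTS:
                errors.append((line_no, f"unknown timepoint {timepoint!r}"))
                continue
            if item_id not in item_map:
                errors.append((line_no, f"unknown item_id {item_id!r}"))
                continue
            if raw_value == "":
                continue  # explicit missing answer
            try:
                value = int(raw_value)
            except ValueError:
                errors.append((line_no, f"non-integer value {raw_value!r}"))
                continue
            item = item_map[item_id]
            if not item.min_value <= value <= item.max_value:
                errors.append(
                    (line_no, f"item {item_id} value {value} outside "
                              f"[{item.min_value}, {item.max_value}]")
                )
                continue
            key = (subject_id, timepoint)
            sheet = sheets.setdefault(
                key, ResponseSheet(subject_id=subject_id, timepoint=timepoint)
            )
            if item_id in sheet.values:
                errors.append(
                    (line_no, f"duplicate entry for ({subject_id}, {timepoint}, {item_id})")
                )
                continue
            sheet.values[item_id] = value

    if errors:
        raise ResponseFileError(path, errors)
    return list(sheets.values())


def write_responses(
    sheets,
    path,
    instrument: Optional[InstrumentDefinition] = None,
) -> None:
    """Write sheets as long-format CSV (unanswered items as empty values)."""
    if instrument is None:
        instrument = load_default_instrument()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESPONSES_HEADER)
        for sheet in sheets:
            for item_id in instrument.item_ids:
                value = sheet.values.get(item_id)
                writer.writerow(
                    [sheet.subject_id, sheet.timepoint, item_id,
                     "" if value is None else value]
                )


def read_metadata(path) -> pd.DataFrame:
    """Read a cohort metadata CSV (one row per subject)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: metadata missing column(s) {', '.join(sorted(missing))}"
        )
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"{path}: duplicate subject ids {dupes[:5]}")
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index=False)


def write_cohort(cohort, out_dir) -> Dict[str, str]:
    """Write a synthetic cohort (metadata, responses, latent truth) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": str(out / "metadata.csv"),
        "responses": str(out / "responses.csv"),
        "latent_health": str(out / "latent_health.csv"),
    }
    write_metadata(cohort.metadata, paths["metadata"])
    write_responses(cohort.sheets, paths["responses"])
    cohort.latent_health.to_csv(paths["latent_health"], index=False)
    return paths
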