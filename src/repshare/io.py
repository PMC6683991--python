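"""Readers and writers for clonotype tables and sample metadata.

Two tabular dialects are supported:

* AIRR Rearrangement TSV — the community-standard per-sequence table with
  ``junction_aa`` and ``duplicate_count`` / ``consensus_count`` columns.
* vdjtools clonotype tables — ``count / freq / cdr3nt / cdr3aa / v / d / j``.

Both are plain tab-delimited text and are parsed with pandas.  Readers
validate into :class:`~repshare.types.ClonotypeRecord`, never invent rows,
and enumerate every skipped row in a :class:`~repshare.types.WarningReport`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .types import (
    ClonotypeRecord,
    DegenerateInputError,
    FormatError,
    InputError,
    SampleMeta,
    Tissue,
    WarningReport,
)

__all__ = ["read_airr", "read_vdjtools", "load_metadata", "write_repertoire"]

logger = logging.getLogger(__name__)

#: AIRR count-column precedence: UMI-consensus pipelines fill duplicate_count;
#: consensus_count is the fallback; otherwise one read per row.
AIRR_COUNT_COLUMNS = ("duplicate_count", "consensus_count")

VDJTOOLS_COLUMNS = ("count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j")


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DegenerateInputError(f"{path}: file is empty") from None
    return df

def _parse_bool(value: str) -> Optional[bool]:
    v = value.strip().lower()
    if v in ("t", "true", "1", "yes", "y"):
        return True
    if v in ("f", "false", "0", "no", "n"):
        return False
    return None


def read_airr(
    path: Union[str, Path],
    sample_id: Optional[str] = None,
    report: Optional[WarningReport] = None,
) -> list[ClonotypeRecord]:
    """Read an AIRR Rearrangement TSV into clonotype records.

    Parameters
    ----------
    path
        Tab-delimited file with a header; ``junction_aa`` is required.
    sample_id
        Overrides any ``sample_id`` column; defaults to the file stem when
        the column is absent.
    report
        Optional warning collector; a fresh one is used (and logged) when
        omitted.

    Returns
    -------
    list of ClonotypeRecord
        One record per well-formed row, ``cdr3_aa`` upper-cased.  Rows with
        an empty CDR3 or invalid letters are skipped and enumerated in the
        report.  Missing count columns default to 1 read per row with a
        warning.
    """
    report = report if report is not None else WarningReport()
    df = _read_table(path)
    if "junction_aa" not in df.columns:
        raise FormatError(f"{path}: required column 'junction_aa' is missing")

    count_col = next((c for c in AIRR_COUNT_COLUMNS if c in df.columns), None)
    if count_col is None:
        report.warn(
            f"{path}: no {'/'.join(AIRR_COUNT_COLUMNS)} column; "
            "defaulting to 1 read per row"
        )

    default_sample = sample_id or Path(path).stem
    records: list[ClonotypeRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        row = row._asdict()
        cdr3 = str(row.get("junction_aa", "")).strip().upper()
        if count_col is not None:
            raw = str(row.get(count_col, "")).strip()
            if raw == "":
                count = 1
                report.warn(f"{path}: row {i}: empty {count_col}; defaulting to 1")
            else:
                try:
                    count = int(float(raw))
                except ValueError:
                    report.skip(i, f"non-numeric {count_col} {raw!r}")
                    continue
        else:
            count = 1
        try:
            rec = ClonotypeRecord(
                sample_id=sample_id or str(row.get("sample_id", "")) or default_sample,
                cdr3_aa=cdr3,
                read_count=count,
                v_call=str(row.get("v_call", "")),
                j_call=str(row.get("j_call", "")),
                cdr3_nt=str(row["junction"]) if row.get("junction") else None,
                isotype=str(row["isotype"]) if row.get("isotype") else None,
                productive=_parse_bool(str(row.get("productive", ""))),
                complete_v=_parse_bool(str(row.get("complete_vdj", ""))),
                v_mutations=int(row["v_mutations"]) if str(row.get("v_mutations", "")).strip() else None,
            )
        except InputError as exc:
            report.skip(i, str(exc))
            continue
        records.append(rec)

    for msg in report.messages:
        logger.warning(msg)
    if report.n_skipped:
        logger.warning(
            "%s: skipped %d malformed rows: %s", path, report.n_skipped,
            report.skipped_rows[:5],
        )
    if not records and report.n_skipped == 0:
        report.warn(f"{path}: table has zero data rows")
    return records


def read_vdjtools(
    path: Union[str, Path],
    sample_id: Optional[str] = None,
    report: Optional[WarningReport] = None,
) -> list[ClonotypeRecord]:
    """Read a vdjtools clonotype table (``count``/``cdr3aa``/``v`` columns).

    The ``freq`` column, when present, is ignored: frequencies are always
    recomputed from counts downstream so they stay consistent after
    filtering.
    """
    report = report if report is not None else WarningReport()
    df = _read_table(path)
    for col in ("count", "cdr3aa"):
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} is missing")

    default_sample = sample_id or Path(path).stem
    records: list[ClonotypeRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        raw = str(row["count"]).strip()
        try:
            count = int(float(raw))
        except ValueError:
            raise FormatError(f"{path}: row {i}: non-numeric count {raw!r}") from None
        try:
            rec = ClonotypeRecord(
                sample_id=default_sample,
                cdr3_aa=str(row["cdr3aa"]).strip().upper(),
                read_count=count,
                v_call=str(row.get("v", "")).replace(".", ""),
                j_call=str(row.get("j", "")).replace(".", ""),
                cdr3_nt=str(row["cdr3nt"]) if row.get("cdr3nt", "").strip(".") else None,
            )
        except InputError as exc:
            report.skip(i, str(exc))
            continue
        records.append(rec)

    if df.shape[0] == 0:
        report.warn(f"{path}: table has zero data rows")
    for msg in report.messages:
        logger.warning(msg)
    return records


def load_metadata(path: Union[str, Path]) -> list[SampleMeta]:
    """Load the sample-metadata table (CSV or TSV, sniffed from the header).

    Columns: sample_id, individual_id, timepoint_days, tissue, population,
    group.  Duplicate sample_ids and unknown tissue values are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DegenerateInputError(f"{path}: file is empty") from None
    required = ("sample_id", "individual_id", "timepoint_days", "tissue",
                "population", "group")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")

    seen: set[str] = set()
    metas: list[SampleMeta] = []
    for i, row in df.iterrows():
        sid = row["sample_id"].strip()
        if sid in seen:
            raise FormatError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        try:
            tissue = Tissue(row["tissue"].strip())
        except ValueError:
            raise FormatError(
                f"{path}: unknown tissue {row['tissue']!r} for sample {sid!r}; "
                f"expected one of {[t.value for t in Tissue]}"
            ) from None
        metas.append(
            SampleMeta(
                sample_id=sid,
                individual_id=row["individual_id"].strip(),
                timepoint_days=int(row["timepoint_days"]),
                tissue=tissue,
                population=row["population"].strip(),
                group=row["group"].strip(),
            )
        )
    return metas


def write_repertoire(rep, path: Union[str, Path]) -> None:
    """Write a collapsed repertoire as a byte-stable vdjtools-style TSV.

    Clonotypes are sorted by descending count, ties broken by lexicographic
    CDR3, so repeated writes of the same repertoire are identical bytes.
    The output round-trips through :func:`read_vdjtools`.
    """
    path = Path(path)
    rows = []
    total = rep.total_reads
    for key in rep.sorted_keys():
        count = rep.clonotypes[key]
        cdr3, v = rep.split_key(key)
        rows.append(
            {
                "count": count,
                "freq": f"{count / total:.10g}" if total else "0",
                "cdr3nt": ".",
                "cdr3aa": cdr3,
                "v": v or ".",
                "d": ".",
                "j": ".",
            }
        )
    df = pd.DataFrame(rows, columns=list(VDJTOOLS_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_airr(records: Iterable[ClonotypeRecord], path: Union[str, Path]) -> None:
    """Write records as an AIRR Rearrangement TSV (one row per record)."""
    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "sequence_id": f"seq{i:06d}",
                "sample_id": r.sample_id,
                "v_call": r.v_call,
                "j_call": r.j_call,
                "junction_aa": r.cdr3_aa,
                "duplicate_count": r.read_count,
                "productive": "" if r.productive is None else str(r.productive).upper()[0],
                "isotype": r.isotype or "",
                "complete_vdj": "" if r.complete_v is None else str(r.complete_v).upper()[0],
                "v_mutations": "" if r.v_mutations is None else r.v_mutations,
            }
        )
    cols = ["sequence_id", "sample_id", "v_call", "j_call", "junction_aa",
            "duplicate_count", "productive", "isotype", "complete_vdj",
            "v_mutations"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False,
                                            lineterminator="\n")
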