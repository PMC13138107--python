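"""Plain-text interchange files shared by all pipeline stages.

Everything is tab-separated with a header row; floats are written at 12
significant digits so round-trips are diff-able and language-agnostic.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .suv import ScanRecord, SUVTable

FLOAT_FMT = "%.12g"
SEP = "\t"

METADATA_COLUMNS = ["scan_id", "group", "cohort", "injected_dose_MBq", "weight_g"]
TAC_COLUMNS = ["scan_id", "organ", "frame_start_min", "frame_end_min", "activity_kBq_per_mL"]


def _require_columns(df: pd.DataFrame, columns: list[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def write_metadata(records: list[ScanRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "scan_id": r.scan_id,
                "group": r.group,
                "cohort": r.cohort,
                "injected_dose_MBq": r.injected_dose,
                "weight_g": r.weight,
            }
            for r in records
        ],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, sep=SEP, index=False, float_format=FLOAT_FMT)


def write_tacs(records: list[ScanRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        if r.tacs is None:
            raise ValueError(f"{r.scan_id}: no TACs to write")
        for organ, tac in r.tacs.items():
            for start, end, value in tac:
                rows.append((r.scan_id, organ, start, end, value))
    pd.DataFrame(rows, columns=TAC_COLUMNS).to_csv(
        path, sep=SEP, index=False, float_format=FLOAT_FMT
    )


def read_records(metadata_path: str | Path, tac_path: str | Path) -> list[ScanRecord]:
    """Rebuild scan records from the metadata + long-format TAC files."""
    meta = pd.read_csv(metadata_path, sep=SEP)
    _require_columns(meta, METADATA_COLUMNS, Path(metadata_path))
    tacs = pd.read_csv(tac_path, sep=SEP)
    _require_columns(tacs, TAC_COLUMNS, Path(tac_path))
    unknown = set(tacs.scan_id) - set(meta.scan_id)
    if unknown:
        raise ValueError(f"TAC rows for scans absent from metadata: {sorted(unknown)[:5]}")
    by_scan = dict(list(tacs.groupby("scan_id", sort=False)))
    records = []
    for row in meta.itertuples(index=False):
        if row.scan_id not in by_scan:
            raise ValueError(f"no TAC rows for scan {row.scan_id!r}")
        sub = by_scan[row.scan_id]
        organ_tacs = {
            organ: g[["frame_start_min", "frame_end_min", "activity_kBq_per_mL"]].to_numpy()
            for organ, g in sub.groupby("organ", sort=False)
        }
        records.append(
            ScanRecord(
                scan_id=row.scan_id,
                group=row.group,
                cohort=str(row.cohort),
                injected_dose=float(row.injected_dose_MBq),
                weight=float(row.weight_g),
                tacs=organ_tacs,
            )
        )
    return records


def write_suv_table(table: SUVTable, path: str | Path) -> None:
    out = table.data.copy()
    out.insert(0, "group", table.groups)
    out.index.name = "scan_id"
    out.to_csv(path, sep=SEP, float_format=FLOAT_FMT)


def read_suv_table(path: str | Path) -> SUVTable:
    df = pd.read_csv(path, sep=SEP, index_col="scan_id")
    if "group" not in df.columns:
        raise ValueError(f"{path}: missing 'group' column")
    groups = df.pop("group")
    return SUVTable(df.astype(float), groups)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep=SEP, float_format=FLOAT_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP, index_col=0)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep=SEP, index=index, float_format=FLOAT_FMT)
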