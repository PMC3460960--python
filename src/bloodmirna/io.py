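"""Readers and writers for the tab-separated on-disk formats.

All files are UTF-8 TSV with one header row.  One spot-table file per
hybridization; the array id is the file stem.  Floats are written with
Python's shortest round-trip representation so read–write cycles are
bit-lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, ProbePanel, SampleSheet, SpotTable
from .errors import ContentError, FormatError

_SPOT_COLUMNS = list(SpotTable.REQUIRED_COLUMNS)
_PANEL_COLUMNS = ["probe_id", "targets", "is_empty", "is_human"]
_SHEET_COLUMNS = list(SampleSheet.REQUIRED_COLUMNS) + list(SampleSheet.OPTIONAL_COLUMNS)


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"{what}: missing required column {col!r}")


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# Probe panel


def write_panel(panel: ProbePanel, path: Path | str) -> None:
    rows = []
    for probe_id, row in panel.table.iterrows():
        rows.append(
            {
                "probe_id": probe_id,
                "targets": ";".join(row["targets"]),
                "is_empty": int(bool(row["is_empty"])),
                "is_human": int(bool(row["is_human"])),
            }
        )
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_panel(path: Path | str) -> ProbePanel:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(frame, _PANEL_COLUMNS, f"panel {path}")
    table = pd.DataFrame(
        {
            "targets": [
                t.split(";") if isinstance(t, str) and t else []
                for t in frame["targets"]
            ],
            "is_empty": frame["is_empty"].astype(int).astype(bool).to_numpy(),
            "is_human": frame["is_human"].astype(int).astype(bool).to_numpy(),
        },
        index=pd.Index(frame["probe_id"], name="probe_id"),
    )
    return ProbePanel(table)


# ---------------------------------------------------------------------------
# Spot tables


def write_spot_tables(tables: Iterable[SpotTable], directory: Path | str) -> List[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for table in tables:
        path = directory / f"{table.array_id}.tsv"
        out = table.data[_SPOT_COLUMNS].copy()
        for col in ("sample_signal", "reference_signal"):
            out[col] = out[col].map(_fmt)
        out.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_spot_tables(paths: Sequence[Path | str], panel: ProbePanel) -> List[SpotTable]:
    tables = []
    for path in paths:
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        _require_columns(frame, _SPOT_COLUMNS, f"spot table {path}")
        frame["probe_id"] = frame["probe_id"].astype(str)
        frame["replicate"] = frame["replicate"].astype(int)
        table = SpotTable(array_id=path.stem, data=frame[_SPOT_COLUMNS])
        table.validate(panel)
        tables.append(table)
    return tables


# ---------------------------------------------------------------------------
# Sample sheet


def write_sample_sheet(sheet: SampleSheet, path: Path | str) -> None:
    out = sheet.table.reindex(columns=_SHEET_COLUMNS).copy()
    out["smoking"] = out["smoking"].astype(int)
    for col in ("age", "wbc", "platelets", "hemoglobin"):
        out[col] = out[col].map(lambda x: "" if pd.isna(x) else _fmt(x))
    out.to_csv(path, sep="\t", index=False)


_TRUE_STRINGS = {"1", "true", "yes"}
_FALSE_STRINGS = {"0", "false", "no"}


def _parse_bool(value: str, what: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise ContentError(f"{what}: cannot interpret {value!r} as a boolean")


def read_sample_sheet(path: Path | str) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(frame, SampleSheet.REQUIRED_COLUMNS, f"sample sheet {path}")
    table = pd.DataFrame(
        {
            "sample_id": frame["sample_id"].astype(str),
            "class": frame["class"].astype(str),
            "control_subtype": frame["control_subtype"].astype(str),
            "age": pd.to_numeric(frame["age"], errors="raise"),
            "gender": frame["gender"].astype(str),
            "smoking": [
                _parse_bool(v, f"sample sheet {path}, column 'smoking'")
                for v in frame["smoking"]
            ],
        }
    )
    for col in SampleSheet.OPTIONAL_COLUMNS:
        if col in frame.columns:
            table[col] = pd.to_numeric(frame[col], errors="coerce")
        else:
            table[col] = np.nan
    ages = table["age"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ages)) or np.any(ages <= 0):
        raise ContentError(f"sample sheet {path}: ages must be positive")
    return SampleSheet(table)


# ---------------------------------------------------------------------------
# Expression matrix

_PROVENANCE_PREFIX = "# provenance: "


def write_expression_matrix(matrix: ExpressionMatrix, path: Path | str) -> None:
    vals = matrix.values.to_numpy(dtype=float)
    if vals.size and not np.all(np.isfinite(vals)):
        raise ContentError("refusing to serialize a matrix with NaN/inf values")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_PROVENANCE_PREFIX + json.dumps(matrix.provenance, sort_keys=True) + "\n")
        samples = [str(s) for s in matrix.values.columns]
        fh.write("\t".join(["probe_id", "expressed"] + samples) + "\n")
        mask = matrix.expressed_mask
        for probe in matrix.values.index:
            expressed = "" if mask is None else str(int(bool(mask.loc[probe])))
            row = [str(probe), expressed] + [_fmt(v) for v in matrix.values.loc[probe]]
            fh.write("\t".join(row) + "\n")


def read_expression_matrix(path: Path | str) -> ExpressionMatrix:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith(_PROVENANCE_PREFIX):
            raise FormatError(f"expression matrix {path}: missing provenance header")
        provenance = json.loads(first[len(_PROVENANCE_PREFIX):])
        frame = pd.read_csv(
            fh, sep="\t", dtype={"probe_id": str}, float_precision="round_trip"
        )
    _require_columns(frame, ["probe_id", "expressed"], f"expression matrix {path}")
    frame = frame.set_index("probe_id")
    mask_col = frame.pop("expressed")
    values = frame.astype(float)
    if mask_col.isna().all():
        mask = None
    else:
        mask = mask_col.astype(int).astype(bool)
        mask.name = None
    return ExpressionMatrix(values=values, expressed_mask=mask, provenance=provenance)
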