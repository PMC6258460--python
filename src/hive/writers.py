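"""Feature-matrix serialization in six formats: CSV, TXT, JSON, EXCEL, SQL, PICKLE.

All text formats share the same layout — a header of ``image_id`` plus the
feature labels, one row per image — and the same rounding contract: values
are rounded half-even to the configured number of fractional digits at write
time only (in-memory matrices keep full precision).  SQL means an embedded
SQLite database file with a single ``features`` table; PICKLE is the native
binary serialization of the FeatureMatrix.
"""

from __future__ import annotations

import json
import pickle
import re
import sqlite3
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from .records import FeatureMatrix

FORMAT_EXTENSIONS = {
    "CSV": ".csv", "TXT": ".txt", "JSON": ".json",
    "EXCEL": ".xlsx", "SQL": ".sqlite", "PICKLE": ".pkl",
}


def _rounded_frame(matrix: FeatureMatrix, decimals: int) -> pd.DataFrame:
    frame = matrix.to_frame()
    return frame.round(decimals)  # numpy round: half-even


def sanitize_identifier(label: str) -> str:
    """Make a feature label a valid SQL column identifier."""
    ident = re.sub(r"\W", "_", label)
    if not ident or ident[0].isdigit():
        ident = "f_" + ident
    return ident


def write_matrix(matrix: FeatureMatrix, fmt: str, decimals: int,
                 destination: str | Path) -> Path:
    """Serialize *matrix* in *fmt* to *destination*; returns the path."""
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("refusing to write an empty feature matrix")
    fmt = fmt.upper()
    if fmt not in FORMAT_EXTENSIONS:
        raise ValueError(f"unknown output format {fmt!r}")
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)

    if fmt in ("CSV", "TXT"):
        frame = _rounded_frame(matrix, decimals)
        sep = "," if fmt == "CSV" else "\t"
        frame.to_csv(destination, sep=sep, float_format=f"%.{decimals}f",
                     lineterminator="\n")
    elif fmt == "JSON":
        frame = _rounded_frame(matrix, decimals)
        payload = {
            "labels": list(matrix.labels),
            "rows": {iid: [round(float(v), decimals) for v in row]
                     for iid, row in zip(matrix.image_ids, frame.to_numpy())},
        }
        destination.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif fmt == "EXCEL":
        frame = _rounded_frame(matrix, decimals)
        frame.to_excel(destination, sheet_name="features")
        _normalize_xlsx(destination)
    elif fmt == "SQL":
        _write_sqlite(matrix, decimals, destination)
    else:  # PICKLE
        with open(destination, "wb") as fh:
            pickle.dump(matrix, fh)
    return destination


def _normalize_xlsx(destination: Path) -> None:
    """Strip wall-clock state from an xlsx so identical matrices give
    identical bytes: fixed zip entry timestamps, fixed document dates."""
    with zipfile.ZipFile(destination) as zin:
        entries = {name: zin.read(name) for name in sorted(zin.namelist())}
    core = entries.get("docProps/core.xml")
    if core is not None:
        text = core.decode("utf-8")
        text = re.sub(r"(<dcterms:(?:created|modified)[^>]*>)[^<]*(</)",
                      r"\g<1>2000-01-01T00:00:00Z\g<2>", text)
        entries["docProps/core.xml"] = text.encode("utf-8")
    with zipfile.ZipFile(destination, "w", zipfile.ZIP_DEFLATED) as zout:
        for name, payload in entries.items():
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zout.writestr(info, payload)


def _write_sqlite(matrix: FeatureMatrix, decimals: int, destination: Path) -> None:
    destination.unlink(missing_ok=True)
    columns = [sanitize_identifier(lbl) for lbl in matrix.labels]
    rounded = np.round(matrix.values, decimals)
    with sqlite3.connect(destination) as conn:
        col_defs = ", ".join(f'"{c}" REAL' for c in columns)
        conn.execute(f"CREATE TABLE features (image_id TEXT PRIMARY KEY, {col_defs})")
        placeholders = ", ".join("?" * (len(columns) + 1))
        conn.executemany(
            f"INSERT INTO features VALUES ({placeholders})",
            ((iid, *map(float, row))
             for iid, row in zip(matrix.image_ids, rounded)),
        )
        conn.commit()


def read_matrix(path: str | Path, fmt: str) -> FeatureMatrix:
    """Read back a matrix written by :func:`write_matrix` (round-trip aid)."""
    fmt = fmt.upper()
    path = Path(path)
    if fmt in ("CSV", "TXT"):
        frame = pd.read_csv(path, sep="," if fmt == "CSV" else "\t",
                            index_col="image_id")
        return FeatureMatrix.from_frame(frame)
    if fmt == "JSON":
        payload = json.loads(path.read_text())
        ids = sorted(payload["rows"])
        values = np.array([payload["rows"][i] for i in ids], dtype=np.float64)
        return FeatureMatrix(image_ids=ids, labels=payload["labels"], values=values)
    if fmt == "EXCEL":
        frame = pd.read_excel(path, sheet_name="features", index_col=0)
        return FeatureMatrix.from_frame(frame)
    if fmt == "SQL":
        with sqlite3.connect(path) as conn:
            frame = pd.read_sql("SELECT * FROM features", conn,
                                index_col="image_id")
        return FeatureMatrix.from_frame(frame)
    if fmt == "PICKLE":
        with open(path, "rb") as fh:
            return pickle.load(fh)
    raise ValueError(f"unknown output format {fmt!r}")
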