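"""Readers/writers for EMR bundles and derived artifacts.

Bundles are file-backed (one CSV per table, JSON-lines for documents)
instead of a SQL database; dates are ISO-8601, encodings UTF-8, and a
write/read round trip reproduces the tables exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synthetic import EmrBundle

_DATE_COLS = {
    "patients": ["birth_date", "death_date"],
    "code_events": ["date"],
    "med_orders": ["date"],
    "lab_results": ["date"],
    "vitals": ["date"],
    "documents": ["date"],
}


def write_bundle(bundle: EmrBundle, out_dir) -> Path:
    """Write a bundle: one CSV per table, documents as JSON-lines."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, tbl in bundle.tables().items():
        if name == "documents":
            with (out / "documents.jsonl").open("w", encoding="utf-8") as fh:
                for row in tbl.itertuples(index=False):
                    fh.write(
                        json.dumps(
                            {
                                "patient_id": row.patient_id,
                                "date": row.date.date().isoformat(),
                                "doc_type": row.doc_type,
                                "text": row.text,
                            }
                        )
                        + "\n"
                    )
            continue
        frame = tbl.copy()
        for col in _DATE_COLS[name]:
            frame[col] = pd.to_datetime(frame[col]).dt.strftime("%Y-%m-%d")
        frame.to_csv(out / f"{name}.csv", index=False)
    return out


def _parse_dates(frame: pd.DataFrame, cols, path) -> pd.DataFrame:
    for col in cols:
        try:
            frame[col] = pd.to_datetime(frame[col], format="%Y-%m-%d")
        except ValueError:
            parsed = pd.to_datetime(frame[col], format="%Y-%m-%d", errors="coerce")
            bad = frame.index[parsed.isna() & frame[col].notna()]
            if len(bad):
                # +2: header line and 1-based file lines
                raise ValueError(
                    f"{path}: malformed date in column {col!r} at line {bad[0] + 2}"
                ) from None
            frame[col] = parsed
    return frame


def read_bundle(in_dir) -> EmrBundle:
    """Read a bundle written by :func:`write_bundle`."""
    src = Path(in_dir)
    tables = {}
    for name in ("patients", "code_events", "med_orders", "lab_results", "vitals"):
        path = src / f"{name}.csv"
        frame = pd.read_csv(path, dtype={"code": str} if name == "code_events" else None)
        tables[name] = _parse_dates(frame, _DATE_COLS[name], path)
    docs_path = src / "documents.jsonl"
    rows = []
    with docs_path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rows.append(json.loads(line))
            except json.JSONDecodeError as err:
                raise ValueError(f"{docs_path}: malformed JSON at line {lineno}: {err}") from None
    docs = pd.DataFrame(rows, columns=["patient_id", "date", "doc_type", "text"])
    tables["documents"] = _parse_dates(docs, ["date"], docs_path)
    return EmrBundle(**tables)


def write_feature_matrix(matrix, out_dir) -> None:
    """Dense CSV plus sparse Matrix-Market with row/column name files."""
    from scipy import io as spio
    from scipy.sparse import csr_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_frame().to_csv(out / "features_dense.csv")
    spio.mmwrite(out / "features.mtx", csr_matrix(matrix.values))
    (out / "features_rows.txt").write_text("\n".join(map(str, matrix.patient_ids)) + "\n")
    (out / "features_cols.txt").write_text("\n".join(matrix.feature_names) + "\n")
    if matrix.provenance is not None:
        matrix.provenance.to_csv(out / "features_provenance.csv", index=False)
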