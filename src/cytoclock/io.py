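"""Plain-text serialization: delimited tables, JSON documents, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

NA_TOKEN = "NA"


def write_table(df: pd.DataFrame, path: Path | str, index_label: str = "visit_id") -> None:
    """Tab-delimited UTF-8 table, one header row, '.' decimal, NA for missing."""
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label=index_label,
              float_format="%.10g", encoding="utf-8")


def read_table(path: Path | str, index_col: int | str = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], index_col=index_col,
                       encoding="utf-8")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {str(c): _jsonable(obj[c]) for c in obj.columns}
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json(doc, path: Path | str) -> None:
    Path(path).write_text(json.dumps(_jsonable(doc), indent=1, sort_keys=True)
                          + "\n", encoding="utf-8")


def read_json(path: Path | str):
    return json.loads(Path(path).read_text(encoding="utf-8"))


def sha256_file(path: Path | str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(run_dir: Path | str, extra: dict | None = None,
                   exclude: tuple[str, ...] = ("manifest.json", "run.log")) -> Path:
    """Content-hash every artifact in a run directory into manifest.json."""
    run_dir = Path(run_dir)
    entries = {}
    for p in sorted(run_dir.rglob("*")):
        if p.is_file() and p.name not in exclude:
            entries[str(p.relative_to(run_dir))] = sha256_file(p)
    doc = {"artifacts": entries}
    if extra:
        doc.update(extra)
    out = run_dir / "manifest.json"
    write_json(doc, out)
    return out
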