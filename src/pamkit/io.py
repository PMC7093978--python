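"""Plain-text table I/O: TSV with commented ``# key=value`` headers.

Every tabular artifact the pipeline writes is a diff-able TSV whose header
comments record provenance (tool version, config hash) so downstream runs
can be traced without a database.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .reads import PamCountTable

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "write_count_table",
    "read_count_table",
]


def config_hash(config: Mapping[str, Any]) -> str:
    """Short stable hash of a JSON-serializable configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(
    path: str | Path,
    frame: pd.DataFrame,
    meta: Mapping[str, Any] | None = None,
    index: bool = True,
) -> Path:
    """Write a TSV with ``# key=value`` comment headers, atomically."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        fh.write(f"# pamkit_version={__version__}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=index)
    tmp.replace(path)
    return path


def read_table(path: str | Path, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_count_table(
    path: str | Path, table: PamCountTable, meta: Mapping[str, Any] | None = None
) -> Path:
    all_meta = {
        "sample_id": table.sample_id,
        "total_reads_used": table.total_reads_used,
        **{f"discarded_{k}": v for k, v in table.discards.items() if v},
        **(meta or {}),
    }
    return write_table(path, table.to_frame(), meta=all_meta)


def read_count_table(path: str | Path, sample_id: str | None = None) -> PamCountTable:
    frame = read_table(path)
    counts = {str(p): int(c) for p, c in frame["count"].items()}
    return PamCountTable.from_counts(sample_id or Path(path).stem, counts)
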