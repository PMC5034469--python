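"""Plain-text interchange IO: TSV tables and BED intervals with provenance.

Every file written by the pipeline starts with ``#``-prefixed header lines
recording the tool version, the config hash and the seed, so any output
can be traced back to the exact run that produced it.  Coordinates are
0-based half-open and coordinate files are sorted by (chrom, start).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = ["write_table", "read_table", "write_bed", "read_bed", "config_hash"]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]


def _header_lines(header: dict | None) -> str:
    if not header:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in header.items())


def write_table(df: pd.DataFrame, path, header: dict | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_bed(df: pd.DataFrame, path, header: dict | None = None) -> None:
    """Write intervals as BED (columns beyond chrom/start/end kept in order)."""
    cols = [c for c in BED_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    out = df[cols + extra].sort_values(["chrom", "start"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        out.to_csv(fh, sep="\t", index=False, header=False)


def read_bed(path, names: list | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if names is None:
        names = BED_COLUMNS[: df.shape[1]] if df.shape[1] <= 6 else (
            BED_COLUMNS + [f"col{i}" for i in range(6, df.shape[1])]
        )
    df.columns = names[: df.shape[1]]
    return df
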