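"""Delimited-text output with a provenance comment line.

Every table written by the package starts with one '#' comment line
recording the tool version and the parameters that produced it, then a
header row.  TSV by default, comma on request.  Readers in this package
skip '#' lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__


def _format_params(params: dict | None) -> str:
    if not params:
        return ""
    return " " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))


def write_table(df: pd.DataFrame, path, params: dict | None = None,
                sep: str = "\t") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# cypflex v{__version__}{_format_params(params)}\n")
        df.to_csv(fh, sep=sep, index=False)
    return path


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(outdir, command: str, config: dict, inputs: list) -> Path:
    """Machine-readable run record: version, resolved config, input digests.

    Deliberately carries no timestamp so identical runs are
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "tool": "cypflex",
        "version": __version__,
        "command": command,
        "config": config,
        "inputs": {str(p): sha256_of(p) for p in inputs if Path(p).is_file()},
    }
    path = outdir / "provenance.json"
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
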