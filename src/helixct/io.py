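"""Tabular output helpers: CSV with '#'-prefixed provenance headers.

Every file written by the CLI embeds the package version, the command
configuration and any seed, so two runs with identical configuration
produce byte-identical numeric content.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def write_csv(path: str | Path, df: pd.DataFrame, metadata: dict) -> None:
    """Write a tidy CSV preceded by '# key: value' metadata lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in metadata.items():
            if isinstance(value, (dict, list)):
                value = json.dumps(value, sort_keys=True)
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_csv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_csv`; returns (frame, metadata)."""
    path = Path(path)
    metadata: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            metadata[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, metadata


def write_json(path: str | Path, payload: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
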