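"""Delimited-text interchange: tables with '#'-prefixed header metadata.

Every stage reads and writes plain comma-separated tables; provenance
(seed, parameters, package version) travels in comment lines so each file is
self-describing and diffable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import EVENT_COLUMNS

__all__ = ["write_table", "read_table", "read_events", "validate_events"]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write ``df`` as CSV with ``# key: value`` metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_table`; returns (frame, metadata)."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    """Check the binding-event table contract; raises on violations.

    Requires positive dwells, known end causes, and delays (where present)
    within [0, dwell_obs] on productive events.
    """
    missing = [c for c in EVENT_COLUMNS if c not in df.columns and c != "condensate_id"]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    dwell = df["dwell_obs"].to_numpy(dtype=float)
    if np.any(~np.isfinite(dwell)) or np.any(dwell <= 0):
        bad = int(np.sum(~np.isfinite(dwell) | (dwell <= 0)))
        raise ValueError(f"{bad} rows have non-positive dwell_obs")
    causes = set(df["end_cause"].unique())
    unknown = causes - {"unbind", "bleach", "censored"}
    if unknown:
        raise ValueError(f"unknown end causes: {sorted(unknown)}")
    delay = df["delay"].to_numpy(dtype=float)
    prod = df["productive"].to_numpy(dtype=bool)
    has_delay = np.isfinite(delay)
    if np.any(has_delay & ~prod):
        raise ValueError("delay present on non-productive events")
    if np.any(has_delay & ((delay < 0) | (delay > dwell))):
        rows = np.nonzero(has_delay & ((delay < 0) | (delay > dwell)))[0]
        raise ValueError(
            f"delays outside [0, dwell_obs] at rows {rows[:10].tolist()}"
        )
    return df


def read_events(path) -> tuple[pd.DataFrame, dict]:
    """Read and validate a binding-event table."""
    df, meta = read_table(path)
    return validate_events(df), meta
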