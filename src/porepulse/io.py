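"""Plain-text file formats, unit parsing, configuration, and run manifests.

All interchange is TSV with ``#``-prefixed key-value header lines, so every
artifact stays inspectable with standard text tools.  Current columns may
be expressed in A, mA, uA, nA or pA (encoded in the column name, e.g.
``current_nA``); values are normalized to amperes on read.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trace import CurrentTrace

__all__ = [
    "FormatError",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "RunManifest",
    "load_config",
    "parse_length",
    "sha256_file",
]

CURRENT_UNITS = {"A": 1.0, "mA": 1e-3, "uA": 1e-6, "nA": 1e-9, "pA": 1e-12}
LENGTH_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "nm": 1e-9}

#: Maximum allowed timestamp jitter, as a fraction of the sampling interval.
TIMESTAMP_JITTER_TOL = 1e-6


class FormatError(ValueError):
    """Malformed input file."""


def parse_length(text: str | float) -> float:
    """Parse a length with an explicit unit suffix ('3nm', '13um') to meters.

    Bare numbers are rejected: silent nm/um mix-ups in the conductance
    relation are exactly what explicit units prevent.
    """
    if isinstance(text, (int, float)):
        raise FormatError(f"length {text!r} needs an explicit unit suffix (m, mm, um, nm)")
    m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*(m|mm|um|nm)\s*", text)
    if not m:
        raise FormatError(f"cannot parse length {text!r}; expected e.g. '3nm' or '13um'")
    return float(m.group(1)) * LENGTH_UNITS[m.group(2)]


def _read_headers(path: Path) -> dict[str, str]:
    headers = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line[1:].partition(":")
                headers[key.strip()] = value.strip()
    return headers


def write_trace(
    path: str | Path,
    trace: CurrentTrace,
    unit: str = "A",
    config_hash: str | None = None,
) -> None:
    """Write a trace as two-column TSV (time_s, current) with metadata headers."""
    if unit not in CURRENT_UNITS:
        raise FormatError(f"unknown current unit {unit!r}")
    path = Path(path)
    scale = CURRENT_UNITS[unit]
    with open(path, "w") as fh:
        fh.write("# porepulse trace v1\n")
        fh.write(f"# sampling_rate_hz: {trace.sampling_rate:.10g}\n")
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        fh.write(f"time_s\tcurrent_{unit}\n")
        np.savetxt(
            fh,
            np.column_stack([trace.times, trace.samples / scale]),
            fmt="%.9f\t%.12e",
            delimiter="\t",
        )


def read_trace(
    path: str | Path,
    dialect: str = "tsv_two_column",
    sampling_rate: float | None = None,
) -> CurrentTrace:
    """Read a trace file, validating sampling uniformity and units.

    ``tsv_two_column`` expects ``time_s`` and ``current_<unit>`` columns;
    ``single_column_with_rate`` expects one current column with the rate in
    a ``# sampling_rate_hz:`` header or the ``sampling_rate`` argument.
    Non-uniform timestamps are rejected with the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("tsv_two_column", "single_column_with_rate"):
        raise FormatError(f"unknown dialect {dialect!r}")
    headers = _read_headers(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    current_cols = [c for c in df.columns if c.startswith("current")]
    if not current_cols:
        raise FormatError(f"{path}: no current column found")
    col = current_cols[0]
    suffix = col.partition("_")[2] or "A"
    if suffix not in CURRENT_UNITS:
        raise FormatError(f"{path}: unknown current unit {suffix!r} in column {col!r}")
    samples = df[col].to_numpy(dtype=float) * CURRENT_UNITS[suffix]

    if dialect == "single_column_with_rate":
        rate = sampling_rate or float(headers.get("sampling_rate_hz", 0))
        if rate <= 0:
            raise FormatError(f"{path}: sampling rate missing for single-column dialect")
        return CurrentTrace(samples, rate)

    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing time_s column")
    times = df["time_s"].to_numpy(dtype=float)
    if times.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(times)
    interval = np.median(dt)
    bad = np.flatnonzero(np.abs(dt - interval) > TIMESTAMP_JITTER_TOL * interval)
    if bad.size:
        n_header = 1 + len([k for k in headers]) + 1  # banner + headers + column line
        raise FormatError(
            f"{path}: non-uniform timestamp at data line {bad[0] + 2} "
            f"(file line ~{n_header + bad[0] + 2}): interval {dt[bad[0]]:g} s "
            f"vs expected {interval:g} s"
        )
    rate = float(headers.get("sampling_rate_hz", 1.0 / interval))
    if abs(rate * interval - 1.0) > 1e-3:
        rate = 1.0 / interval
    return CurrentTrace(samples, rate, start_time=float(times[0]))


def write_events(path: str | Path, table: pd.DataFrame) -> None:
    """Write an event feature table as TSV, with dwell also in ms."""
    out = table.copy()
    if "dwell_s" in out.columns and "dwell_ms" not in out.columns:
        out["dwell_ms"] = out["dwell_s"] * 1e3
    out.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "dwell_s" not in df.columns and "dwell_ms" in df.columns:
        df["dwell_s"] = df["dwell_ms"] * 1e-3
    return df


def load_config(path: str | Path) -> dict:
    """Load a flat key-value YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted once per pipeline run."""

    config: dict
    seeds: dict
    input_hashes: dict = field(default_factory=dict)
    tool_version: str = ""
    stage_counts: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seeds": self.seeds,
                    "input_hashes": self.input_hashes,
                    "tool_version": self.tool_version,
                    "stage_counts": self.stage_counts,
                },
                fh,
                indent=2,
                default=str,
            )
            fh.write("\n")
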