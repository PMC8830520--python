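"""Delimited-text series format shared by all modules.

A series file is UTF-8 CSV with ``#``-prefixed ``key=value`` header lines
carrying provenance metadata, then a header row ``gamma_t,phi,phi_dot`` and
one sample per row at full float precision.  Processed streams use the same
layout with extra columns.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

__all__ = ["write_series", "read_series"]

_KNOWN_META = (
    "shear_stress_dyne_cm2",
    "body_type",
    "aspect_ratio",
    "seed",
    "sample_interval",
)


def write_series(path, frame: pd.DataFrame, metadata: dict | None = None) -> None:
    """Write a (time, angle, speed, ...) frame with ``# key=value`` header."""
    path = Path(path)
    lines = []
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}={value}")
    buf = _io.StringIO()
    frame.to_csv(buf, index=False, float_format="%.17g")
    path.write_text("\n".join(lines) + ("\n" if lines else "") + buf.getvalue())


def read_series(path) -> tuple[pd.DataFrame, dict]:
    """Read a series file; returns (frame, metadata).

    Numeric-looking metadata values are converted to int/float.
    """
    path = Path(path)
    metadata: dict = {}
    header_rows = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_rows += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                metadata[key.strip()] = _coerce(value.strip())
    frame = pd.read_csv(path, skiprows=header_rows, float_precision="round_trip")
    return frame, metadata


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value
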