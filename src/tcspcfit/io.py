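"""Delimited-text round-tripping of histograms and titration series.

Trace format (``.tsv``): comment header lines prefixed ``#`` carry the grid
and labels, followed by two tab-separated columns (channel index, counts)::

    # tcspc-trace v1
    # dwell_ns: 0.04
    # t0_channel: 64
    # kind: decay
    # meta: {"position": 24}
    0\t3
    1\t5
    ...

Titration series use the same header style with columns
(concentration, response[, error]). Both writers round-trip losslessly
through their readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import ChannelGrid, DecayTrace, InvalidParameterError
from .titration import TitrationSeries

TRACE_MAGIC = "# tcspc-trace v1"
SERIES_MAGIC = "# tcspc-series v1"


class TraceParseError(ValueError):
    """Malformed trace/series file; message carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def _parse_headers(lines: list[str]) -> tuple[dict, int]:
    """Collect '# key: value' headers; returns (headers, first data line idx)."""
    headers: dict[str, str] = {}
    idx = 0
    for idx, line in enumerate(lines):
        stripped = line.strip()
        if not stripped.startswith("#"):
            break
        body = stripped.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            headers[key.strip()] = value.strip()
    else:
        idx = len(lines)
    return headers, idx


def write_trace(trace: DecayTrace, path: str | Path) -> None:
    """Write a trace as delimited text with a self-describing header."""
    path = Path(path)
    lines = [
        TRACE_MAGIC,
        f"# dwell_ns: {trace.grid.dwell!r}",
        f"# t0_channel: {trace.grid.t0_channel}",
        f"# kind: {trace.kind}",
        f"# meta: {json.dumps(trace.meta, sort_keys=True)}",
    ]
    for k, c in enumerate(trace.counts):
        # integers stay integers; floats keep full precision
        lines.append(f"{k}\t{int(c) if float(c).is_integer() else repr(float(c))}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> DecayTrace:
    """Read a trace written by :func:`write_trace` (lossless round-trip)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    headers, start = _parse_headers(lines)
    if "dwell_ns" not in headers:
        raise TraceParseError(f"missing 'dwell_ns' header in {path}", line_number=1)
    if "t0_channel" not in headers:
        raise TraceParseError(f"missing 't0_channel' header in {path}", line_number=1)
    counts = []
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TraceParseError(f"expected 2 columns, got {len(parts)}", ln)
        try:
            channel = int(parts[0])
            value = float(parts[1])
        except ValueError as err:
            raise TraceParseError(str(err), ln) from None
        if channel != len(counts):
            raise TraceParseError(
                f"non-contiguous channel index {channel} (expected {len(counts)})", ln
            )
        if value < 0:
            raise TraceParseError(f"negative count {value}", ln)
        counts.append(value)
    if not counts:
        raise TraceParseError(f"no data rows in {path}")
    grid = ChannelGrid(
        n_channels=len(counts),
        dwell=float(headers["dwell_ns"]),
        t0_channel=int(headers["t0_channel"]),
    )
    meta = json.loads(headers.get("meta", "{}"))
    kind = headers.get("kind", "decay")
    try:
        return DecayTrace(grid=grid, counts=np.array(counts), kind=kind, meta=meta)
    except InvalidParameterError as err:
        raise TraceParseError(str(err)) from err


def write_series(series: TitrationSeries, path: str | Path) -> None:
    """Write a titration series as delimited text."""
    path = Path(path)
    lines = [
        SERIES_MAGIC,
        f"# kind: {series.kind}",
        f"# meta: {json.dumps(series.meta, sort_keys=True)}",
        "# columns: concentration\tresponse\terror",
    ]
    errors = (
        series.response_errors
        if series.response_errors is not None
        else np.full(len(series), np.nan)
    )
    for c, r, e in zip(series.concentrations, series.responses, errors):
        lines.append(f"{float(c)!r}\t{float(r)!r}\t{float(e)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_series(path: str | Path) -> TitrationSeries:
    """Read a titration series written by :func:`write_series`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    headers, start = _parse_headers(lines)
    if "kind" not in headers:
        raise TraceParseError(f"missing 'kind' header in {path}", line_number=1)
    conc, resp, err = [], [], []
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise TraceParseError(f"expected 2-3 columns, got {len(parts)}", ln)
        try:
            conc.append(float(parts[0]))
            resp.append(float(parts[1]))
            err.append(float(parts[2]) if len(parts) == 3 else float("nan"))
        except ValueError as e:
            raise TraceParseError(str(e), ln) from None
    if not conc:
        raise TraceParseError(f"no data rows in {path}")
    errors = np.array(err)
    return TitrationSeries(
        concentrations=np.array(conc),
        responses=np.array(resp),
        response_errors=None if np.all(np.isnan(errors)) else errors,
        kind=headers["kind"],
        meta=json.loads(headers.get("meta", "{}")),
    )
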