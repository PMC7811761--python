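"""Minimal FCS 3.1 reader/writer.

Supports what the assay pipeline needs: list-mode ($MODE L) files with
floating-point data ($DATATYPE F or D), a single dataset, and $PnN channel
names. Integer data and multi-dataset files are out of scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_fcs", "write_fcs", "FCSFormatError"]


class FCSFormatError(ValueError):
    """Raised when a file cannot be parsed as FCS, naming the offending segment."""


_DELIM = "/"


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    text = raw.decode("utf-8", errors="replace")
    if not text:
        raise FCSFormatError("TEXT segment: empty")
    delim = text[0]
    # Double-delimiter escaping is not handled; our writer never emits it.
    parts = text.strip(delim).split(delim)
    if len(parts) < 2:
        raise FCSFormatError("TEXT segment: no key/value pairs")
    if len(parts) % 2 == 1:
        parts = parts[:-1]
    return {parts[i].strip(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path: str | Path) -> tuple[list[str], np.ndarray, dict[str, str]]:
    """Read an FCS 3.0/3.1 file.

    Returns ``(channel_names, values, keywords)`` with values as an
    (events x channels) float64 array in the file's raw (linear) units.
    """
    data = Path(path).read_bytes()
    if len(data) < 58:
        raise FCSFormatError("HEADER: file too short to contain an FCS header")
    version = data[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise FCSFormatError(f"HEADER: unsupported version {version!r}")
    try:
        text_start = int(data[10:18])
        text_end = int(data[18:26])
    except ValueError as exc:
        raise FCSFormatError("HEADER: non-numeric TEXT segment offsets") from exc
    kw = _parse_text_segment(data[text_start : text_end + 1])

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
    except KeyError as exc:
        raise FCSFormatError(f"TEXT segment: missing required keyword {exc}") from exc
    datatype = kw.get("$DATATYPE", "F")
    if datatype not in ("F", "D"):
        raise FCSFormatError(f"DATA segment: unsupported $DATATYPE {datatype!r}")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if datatype == "F" else 8

    data_start = int(kw.get("$BEGINDATA", 0)) or int(data[26:34] or 0)
    data_end = int(kw.get("$ENDDATA", 0)) or int(data[34:42] or 0)
    n_bytes = n_par * n_tot * itemsize
    if data_end - data_start + 1 < n_bytes:
        raise FCSFormatError("DATA segment: shorter than $PAR x $TOT events")
    raw = data[data_start : data_start + n_bytes]
    dtype = np.dtype(f"{endian}f{itemsize}")
    values = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(np.float64)

    channels = []
    for i in range(1, n_par + 1):
        channels.append(kw.get(f"$P{i}N", f"P{i}"))
    return channels, values, kw


def write_fcs(
    path: str | Path,
    channels: list[str],
    values: np.ndarray,
    extra_keywords: dict[str, str] | None = None,
) -> Path:
    """Write an FCS 3.1 file (list mode, 32-bit float, little endian)."""
    values = np.asarray(values, dtype=np.float32)
    n_tot, n_par = values.shape
    if n_par != len(channels):
        raise ValueError("channel count does not match value columns")

    kw: dict[str, str] = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, name in enumerate(channels, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(np.ceil(float(np.abs(values).max() + 1))) if n_tot else 1024)
    if extra_keywords:
        kw.update(extra_keywords)

    header_len = 58
    data_bytes = values.astype("<f4").tobytes()

    # The TEXT segment must state absolute DATA offsets; sizes are resolved by
    # writing with placeholder offsets of fixed width.
    def render_text(begin_data: int, end_data: int) -> bytes:
        items = dict(kw)
        items["$BEGINDATA"] = str(begin_data).rjust(12)
        items["$ENDDATA"] = str(end_data).rjust(12)
        body = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in items.items()) + _DELIM
        return body.encode("utf-8")

    text = render_text(0, 0)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(data_bytes) - 1
    text = render_text(data_start, data_end)
    assert text_end == text_start + len(text) - 1  # fixed-width placeholders

    def field(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # oversized offsets resolved through TEXT keywords
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + field(text_start) + field(text_end)
    header += field(data_start if data_end <= 99999999 else 0)
    header += field(data_end if data_end <= 99999999 else 0)
    header += field(0) + field(0)
    assert len(header) == header_len

    out = Path(path)
    out.write_bytes(header + text + data_bytes)
    return out
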