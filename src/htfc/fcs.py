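"""Minimal FCS 3.0 I/O for list-mode float data.

Writes the subset of the standard the pipeline needs: an ASCII HEADER
with segment offsets, a delimited TEXT segment carrying $PnN channel
names, and a little-endian float32 DATA segment in list mode.  The reader
accepts files in that dialect (single data set, $DATATYPE F, $MODE L,
byte order 1,2,3,4 or 4,3,2,1) and reports a byte offset with every
format error.

A gzip-CSV tabular fallback (header row of channel names + sidecar JSON
metadata) is provided for plain-text interchange.
"""

from __future__ import annotations

import gzip
import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import EventTable

__all__ = ["write_fcs", "read_fcs", "FcsFormatError", "write_tabular", "read_tabular"]

_DELIM = b"/"


class FcsFormatError(ValueError):
    """Malformed FCS file; message carries the byte offset of the problem."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at byte offset {offset})"
        super().__init__(message)
        self.offset = offset


def _escape(value: str) -> str:
    return value.replace(_DELIM.decode(), _DELIM.decode() * 2)


def write_fcs(events: EventTable, path: str | Path) -> None:
    """Write an EventTable as an FCS 3.0 file (float32 list mode)."""
    data = events.data.to_numpy(dtype="<f4")
    n_events, n_par = data.shape
    databytes = data.tobytes()

    keywords: list[tuple[str, str]] = [
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$BYTEORD", "1,2,3,4"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_events)),
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
    ]
    for i, ch in enumerate(events.channels, start=1):
        keywords += [
            (f"$P{i}N", _escape(ch)),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(max(1, np.ceil(events.data.iloc[:, i - 1].max()))))),
        ]
    for key in ("plate", "well", "sample_id", "master_seed"):
        if events.metadata.get(key) is not None:
            keywords.append((f"HTFC_{key.upper()}", _escape(str(events.metadata[key]))))

    # TEXT must embed its own and DATA's offsets; sizes shift with the digits,
    # so iterate until the layout is stable.
    header_len = 58
    begin_text = header_len
    placeholder = [("$BEGINDATA", "0"), ("$ENDDATA", "0")]
    for _ in range(8):
        body = _DELIM
        for k, v in keywords + placeholder:
            body += k.encode() + _DELIM + v.encode() + _DELIM
        end_text = begin_text + len(body) - 1
        begin_data = end_text + 1
        end_data = begin_data + len(databytes) - 1
        new_placeholder = [("$BEGINDATA", str(begin_data)), ("$ENDDATA", str(end_data))]
        if new_placeholder == placeholder:
            break
        placeholder = new_placeholder
    else:  # pragma: no cover - layout always converges in <= 2 rounds
        raise RuntimeError("FCS offset layout failed to converge")

    header = b"FCS3.0    "
    for off in (begin_text, end_text, begin_data, end_data, 0, 0):
        field = str(off).rjust(8).encode()
        if len(field) > 8:
            field = b"       0"  # oversized segment: offsets live in TEXT only
        header += field
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(body)
        fh.write(databytes)


def _parse_text_segment(raw: bytes, begin: int) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment", begin)
    delim = raw[:1]
    parts = raw[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise FcsFormatError("odd number of TEXT tokens", begin)
    return {
        parts[i].decode("utf-8", "replace").strip(): parts[i + 1].decode("utf-8", "replace")
        for i in range(0, len(parts), 2)
    }


def read_fcs(path: str | Path) -> EventTable:
    """Read an FCS 3.0 file written in this module's dialect."""
    blob = Path(path).read_bytes()
    if len(blob) < 58:
        raise FcsFormatError("file shorter than FCS header", 0)
    if not blob.startswith(b"FCS3.0"):
        raise FcsFormatError(f"bad magic {blob[:6]!r}", 0)
    try:
        begin_text = int(blob[10:18])
        end_text = int(blob[18:26])
    except ValueError as exc:
        raise FcsFormatError(f"unparseable HEADER offsets: {exc}", 10) from None
    text = _parse_text_segment(blob[begin_text : end_text + 1], begin_text)

    required = ["$DATATYPE", "$MODE", "$PAR", "$TOT", "$BYTEORD", "$BEGINDATA", "$ENDDATA"]
    for key in required:
        if key not in text:
            raise FcsFormatError(f"missing required TEXT keyword {key}", begin_text)
    if text["$DATATYPE"] != "F":
        raise FcsFormatError(f"unsupported $DATATYPE {text['$DATATYPE']!r}", begin_text)
    if text["$MODE"] != "L":
        raise FcsFormatError(f"unsupported $MODE {text['$MODE']!r}", begin_text)
    byteord = text["$BYTEORD"].strip()
    if byteord == "1,2,3,4":
        dtype = "<f4"
    elif byteord == "4,3,2,1":
        dtype = ">f4"
    else:
        raise FcsFormatError(f"unsupported $BYTEORD {byteord!r}", begin_text)

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    channels = []
    for i in range(1, n_par + 1):
        if f"$P{i}N" not in text:
            raise FcsFormatError(f"missing channel name keyword $P{i}N", begin_text)
        channels.append(text[f"$P{i}N"])

    begin_data = int(text["$BEGINDATA"])
    end_data = int(text["$ENDDATA"])
    expected = n_par * n_tot * 4
    avail = end_data - begin_data + 1
    if avail != expected or len(blob) < end_data + 1:
        raise FcsFormatError(
            f"DATA segment holds {avail} bytes, expected {expected}", begin_data
        )
    data = np.frombuffer(blob[begin_data : end_data + 1], dtype=dtype).reshape(
        n_tot, n_par
    )
    meta = {
        k.removeprefix("HTFC_").lower(): v for k, v in text.items() if k.startswith("HTFC_")
    }
    if "master_seed" in meta:
        meta["master_seed"] = int(meta["master_seed"])
    return EventTable(
        data=pd.DataFrame(np.asarray(data, dtype=float), columns=channels),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Tabular fallback: gzip CSV + sidecar JSON
# ---------------------------------------------------------------------------

def write_tabular(events: EventTable, path: str | Path) -> None:
    """Gzip-CSV fallback; metadata goes to a ``.json`` sidecar."""
    path = Path(path)
    with gzip.open(path, "wt", newline="") as fh:
        events.data.to_csv(fh, index=False, float_format="%.6g")
    meta = {
        k: v
        for k, v in events.metadata.items()
        if isinstance(v, (str, int, float, bool, type(None)))
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_tabular(path: str | Path) -> EventTable:
    path = Path(path)
    with gzip.open(path, "rt") as fh:
        data = pd.read_csv(fh)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return EventTable(data=data, metadata=meta)
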