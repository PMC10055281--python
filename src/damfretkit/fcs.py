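"""Minimal FCS 3.0/3.1 LIST-mode reader and writer.

Supports the subset of the standard this pipeline produces and consumes:
LIST mode (``$MODE=L``), floating-point (``$DATATYPE=F``, 32-bit) or integer
(``$DATATYPE=I``) data, little- or big-endian.  Event data are exchanged as a
:class:`pandas.DataFrame` with one column per channel, named by ``$PnN``.

Unsupported keywords raise :class:`FCSFormatError` naming the offending
keyword rather than guessing.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FCSFormatError", "read_fcs", "write_fcs"]

_DELIM = "/"


class FCSFormatError(ValueError):
    """Raised for files outside the supported FCS subset."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    # strip leading/trailing delimiter; double-delimiter escapes are not
    # produced by this writer and are rare in practice -> not supported
    parts = body.strip(delim).split(delim)
    if len(parts) % 2 != 0:
        parts = parts[:-1]
    kv = {}
    for key, val in zip(parts[::2], parts[1::2]):
        kv[key.strip().upper()] = val.strip()
    return kv


def read_fcs(path: str | Path) -> pd.DataFrame:
    """Read an FCS 3.0/3.1 LIST-mode file into a DataFrame of events."""
    data = Path(path).read_bytes()
    version = data[:6].decode("latin-1", errors="replace")
    if not version.startswith("FCS3"):
        raise FCSFormatError(f"unsupported FCS version {version!r}")

    def _offset(segment: slice) -> int:
        return int(data[segment].decode("latin-1").strip() or 0)

    text_start = _offset(slice(10, 18))
    text_end = _offset(slice(18, 26))
    data_start = _offset(slice(26, 34))
    data_end = _offset(slice(34, 42))

    kv = _parse_text_segment(data[text_start : text_end + 1])
    if data_start == 0:
        data_start = int(kv.get("$BEGINDATA", 0))
        data_end = int(kv.get("$ENDDATA", 0))

    mode = kv.get("$MODE", "")
    if mode != "L":
        raise FCSFormatError(f"$MODE={mode!r} not supported (only LIST mode 'L')")
    datatype = kv.get("$DATATYPE", "")
    if datatype not in ("F", "I"):
        raise FCSFormatError(f"$DATATYPE={datatype!r} not supported (only 'F' or 'I')")

    byteord = kv.get("$BYTEORD", "1,2,3,4")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FCSFormatError(f"$BYTEORD={byteord!r} not supported")

    n_par = int(kv["$PAR"])
    n_tot = int(kv["$TOT"])
    names = [kv.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    bits = [int(kv.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)]
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FCSFormatError("$PnB must be 32 for $DATATYPE=F")
        dtype = np.dtype(f"{endian}f4")
    else:
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise FCSFormatError("$PnB must be uniform 16 or 32 for $DATATYPE=I")
        dtype = np.dtype(f"{endian}u{bits[0] // 8}")

    raw = data[data_start : data_end + 1]
    expected = n_par * n_tot * dtype.itemsize
    if len(raw) < expected:
        raise FCSFormatError(
            f"DATA segment holds {len(raw)} bytes, need {expected} "
            f"($PAR={n_par}, $TOT={n_tot})"
        )
    values = np.frombuffer(raw[:expected], dtype=dtype).reshape(n_tot, n_par)
    return pd.DataFrame(values.astype(np.float64), columns=names)


def write_fcs(table: pd.DataFrame, path: str | Path, extra_keywords: dict | None = None) -> None:
    """Write a DataFrame of events as FCS 3.1, LIST mode, 32-bit float."""
    if table.shape[1] == 0:
        raise ValueError("cannot write an FCS file with no channels")
    values = np.ascontiguousarray(table.to_numpy(dtype=np.float32))
    n_tot, n_par = values.shape
    data_bytes = values.tobytes()

    keywords: dict[str, str] = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, name in enumerate(table.columns, start=1):
        col_max = float(np.max(values[:, i - 1], initial=0.0))
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(col_max, 1.0)) + 1)
    if extra_keywords:
        keywords.update({str(k): str(v) for k, v in extra_keywords.items()})

    header_len = 58
    # iterate: TEXT length depends on the offsets written inside it
    begin_data = 0
    for _ in range(8):
        kv = dict(keywords)
        kv["$BEGINDATA"] = str(begin_data)
        kv["$ENDDATA"] = str(begin_data + len(data_bytes) - 1)
        kv["$BEGINANALYSIS"] = "0"
        kv["$ENDANALYSIS"] = "0"
        kv["$BEGINSTEXT"] = "0"
        kv["$ENDSTEXT"] = "0"
        text = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in kv.items()) + _DELIM
        text_bytes = text.encode("latin-1")
        new_begin = header_len + len(text_bytes)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    text_start = header_len
    text_end = text_start + len(text_bytes) - 1
    data_start = begin_data
    data_end = data_start + len(data_bytes) - 1

    def fmt(n: int) -> bytes:
        s = str(n)
        if len(s) > 8:
            s = "0"  # real offsets live in $BEGINDATA/$ENDDATA
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + fmt(text_start) + fmt(text_end) + fmt(data_start) + fmt(data_end) + fmt(0) + fmt(0)
    assert len(header) == header_len
    Path(path).write_bytes(header + text_bytes + data_bytes)
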