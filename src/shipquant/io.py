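"""Event-table I/O: CSV (canonical, lossless) and minimal FCS 3.1.

CSV round-trips the full event table including metadata columns.  FCS holds
only numeric parameters, so string metadata is not representable there; the
FCS writer stores every numeric column as a parameter (list mode, float32,
little-endian, ``$PnN`` channel names) and the reader returns them.  The FCS
support is a small, self-contained implementation of the FCS 3.1 container
(HEADER + TEXT + DATA segments), sufficient for round-tripping simulated
event data; it does not aim to cover the full standard (no ANALYSIS segment,
no log-amplified ``$PnE``, single dataset per file).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = ["write_events", "read_events", "write_fcs", "read_fcs"]

_DELIM = "/"
_HEADER_LEN = 58


def write_fcs(path: str | os.PathLike, df: pd.DataFrame) -> None:
    """Write the numeric columns of ``df`` as an FCS 3.1 file (float32, list mode)."""
    numeric = df.select_dtypes(include=[np.number, bool]).astype(np.float32)
    if numeric.shape[1] == 0 or numeric.shape[0] == 0:
        raise ParameterError("event table has no numeric data to write")
    data = np.ascontiguousarray(numeric.to_numpy(dtype="<f4"))
    n_tot, n_par = data.shape

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_tot),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(numeric.columns, start=1):
        col = data[:, i - 1]
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(np.ceil(float(col.max()))) + 1 if col.size else 1)

    # $BEGINDATA/$ENDDATA are zero-padded to fixed width so the TEXT length is
    # independent of their eventual values (single-pass offset computation).
    def text_bytes(begin: int, end: int) -> bytes:
        kw = dict(keywords)
        kw["$BEGINDATA"] = f"{begin:010d}"
        kw["$ENDDATA"] = f"{end:010d}"
        parts = [_DELIM]
        for key, value in kw.items():
            parts.append(f"{key}{_DELIM}{value}{_DELIM}")
        return "".join(parts).encode("ascii")

    text_len = len(text_bytes(0, 0))
    text_begin = _HEADER_LEN
    text_end = text_begin + text_len - 1
    data_begin = text_begin + text_len
    data_end = data_begin + data.nbytes - 1
    if data_end > 99_999_999:
        # FCS 3.1 allows 0 in the header with offsets in TEXT for large files.
        header_data_begin = header_data_end = 0
    else:
        header_data_begin, header_data_end = data_begin, data_end

    header = (
        b"FCS3.1    "
        + f"{text_begin:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{header_data_begin:>8d}".encode()
        + f"{header_data_end:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes(data_begin, data_end))
        fh.write(data.tobytes())


def read_fcs(path: str | os.PathLike) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read an FCS 3.0/3.1 file written by :func:`write_fcs`.

    Returns ``(events, keywords)``.  Supports list-mode float32/float64 data
    with a uniform ``$PnB``; that covers this package's own output and plain
    exports from common acquisition software.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_LEN or not raw[:6].startswith(b"FCS3"):
        raise ParameterError(f"{path}: not an FCS 3.x file")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_begin : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    tokens = text[1:].split(delim)
    kw = {
        tokens[i].strip().upper(): tokens[i + 1]
        for i in range(0, len(tokens) - 1, 2)
        if tokens[i].strip()
    }
    data_begin = int(raw[26:34] or 0) or int(kw["$BEGINDATA"])
    data_end = int(raw[34:42] or 0) or int(kw["$ENDDATA"])
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    order = "<" if byteord.startswith("1") else ">"
    if dtype == "F":
        np_dtype = np.dtype(order + "f4")
    elif dtype == "D":
        np_dtype = np.dtype(order + "f8")
    else:
        raise ParameterError(f"unsupported $DATATYPE {dtype!r} (only F/D)")
    buf = raw[data_begin : data_end + 1]
    values = np.frombuffer(buf, dtype=np_dtype, count=n_tot * n_par)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    events = pd.DataFrame(values.reshape(n_tot, n_par).astype(float), columns=names)
    return events, kw


def write_events(table: pd.DataFrame, path: str | os.PathLike, format: str = "csv") -> None:
    """Write an event table to ``path`` as ``csv`` (lossless) or ``fcs``."""
    if table.empty:
        raise ParameterError("event table is empty")
    fmt = format.lower()
    if fmt == "csv":
        table.to_csv(path, index=False)
    elif fmt == "fcs":
        write_fcs(path, table)
    else:
        raise ParameterError(f"unknown format {format!r}: use 'csv' or 'fcs'")


def read_events(path: str | os.PathLike, format: str | None = None) -> pd.DataFrame:
    """Read an event table; format inferred from the suffix unless given."""
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "fcs":
        events, _ = read_fcs(path)
        return events
    raise ParameterError(f"unknown format {fmt!r}: use 'csv' or 'fcs'")
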