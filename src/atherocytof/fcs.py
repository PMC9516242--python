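"""Minimal FCS 3.0/3.1 reader and writer.

Supports list-mode float data (``$DATATYPE F``, ``$MODE L``), which is what
this pipeline writes and what CyTOF acquisition software emits after
conversion.  Channel marker names go to ``$PnN``/``$PnS``; channel roles are
stored in the non-standard ``PnROLE`` keyword and recovered on read (falling
back to name-based inference).

No pre-installed library in the target environment parses FCS, hence this
small self-contained implementation.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .events import CellEventMatrix, Channel, infer_role

_DELIM = "/"


def _escape(value: str) -> str:
    return value.replace(_DELIM, _DELIM * 2)


def write_fcs(path: str | Path, events: CellEventMatrix) -> None:
    """Write one sample as an FCS 3.0 list-mode file (doubles, lossless)."""
    data = np.ascontiguousarray(events.data, dtype="<f8")
    n_events, n_par = data.shape

    text: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "D",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
        "$FIL": _escape(events.sample_id),
    }
    for i, ch in enumerate(events.channels, start=1):
        text[f"$P{i}N"] = _escape(ch.name)
        if ch.mass:
            text[f"$P{i}S"] = _escape(ch.mass)
        text[f"$P{i}B"] = "64"
        text[f"$P{i}E"] = "0,0"
        text[f"$P{i}R"] = str(int(max(float(data[:, i - 1].max(initial=0.0)), 1)) + 1)
        text[f"P{i}ROLE"] = ch.role

    # Two-pass offset computation: segment positions depend on the length of
    # the TEXT segment, which itself contains the offsets.
    data_bytes = data.tobytes()

    def render(begin_data: int, end_data: int) -> bytes:
        kv = dict(text)
        kv["$BEGINDATA"] = str(begin_data)
        kv["$ENDDATA"] = str(end_data)
        parts = [_DELIM]
        for key in sorted(kv):
            parts.append(f"{key}{_DELIM}{kv[key]}{_DELIM}")
        return "".join(parts).encode("utf-8")

    header_len = 58
    begin_text = header_len
    guess = render(0, 0)
    for _ in range(10):
        begin_data = begin_text + len(guess)
        end_data = begin_data + len(data_bytes) - 1
        nxt = render(begin_data, end_data)
        if len(nxt) == len(guess):
            guess = nxt
            break
        guess = nxt
    end_text = begin_text + len(guess) - 1

    header = (
        f"FCS3.0    "
        f"{begin_text:>8d}{end_text:>8d}"
        f"{begin_data:>8d}{end_data:>8d}"
        f"{0:>8d}{0:>8d}"
    ).encode("ascii")
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(guess)
        fh.write(data_bytes)


def _parse_text(raw: bytes) -> dict[str, str]:
    txt = raw.decode("utf-8", errors="replace")
    delim = txt[0]
    # split on single delimiters; doubled delimiters are escapes
    tokens: list[str] = []
    buf: list[str] = []
    i = 1
    while i < len(txt):
        c = txt[i]
        if c == delim:
            if i + 1 < len(txt) and txt[i + 1] == delim:
                buf.append(delim)
                i += 2
                continue
            tokens.append("".join(buf))
            buf = []
            i += 1
        else:
            buf.append(c)
            i += 1
    if buf:
        tokens.append("".join(buf))
    pairs = {}
    for k, v in zip(tokens[::2], tokens[1::2]):
        pairs[k.strip().upper() if k.startswith("$") else k.strip()] = v
    return pairs


def read_fcs(path: str | Path, sample_id: str | None = None) -> CellEventMatrix:
    """Read an FCS 3.0/3.1 list-mode file into a :class:`CellEventMatrix`."""
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(58)
        if not header[:3] == b"FCS":
            raise IOError(f"{path}: not an FCS file")
        begin_text = int(header[10:18])
        end_text = int(header[18:26])
        begin_data = int(header[26:34])
        end_data = int(header[34:42])
        fh.seek(begin_text)
        text = _parse_text(fh.read(end_text - begin_text + 1))
        if begin_data == 0:
            begin_data = int(text["$BEGINDATA"])
            end_data = int(text["$ENDDATA"])
        fh.seek(begin_data)
        raw = fh.read(end_data - begin_data + 1)

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    if datatype == "F":
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
    else:
        raise IOError(f"{path}: unsupported $DATATYPE {datatype!r}")

    expected = n_par * n_tot * dtype.itemsize
    if len(raw) < expected:
        raise IOError(f"{path}: truncated data segment")
    data = np.frombuffer(raw[:expected], dtype=dtype).reshape(n_tot, n_par)

    channels = []
    for i in range(1, n_par + 1):
        name = text.get(f"$P{i}N", f"P{i}")
        mass = text.get(f"$P{i}S", "")
        role = text.get(f"P{i}ROLE", infer_role(name))
        channels.append(Channel(name=name, mass=mass, role=role))

    return CellEventMatrix(
        sample_id=sample_id or text.get("$FIL", path.stem),
        data=np.array(data, dtype=float),
        channels=channels,
    )


def _read_header_offsets(path: str | Path) -> tuple[int, int]:
    with open(path, "rb") as fh:
        header = fh.read(58)
    return struct.unpack(">2i", header[10:18] + header[18:26])  # pragma: no cover
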