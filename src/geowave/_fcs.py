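"""Minimal FCS 3.0/3.1 list-mode reader.

Reads the HEADER and TEXT segments of a Flow Cytometry Standard file and
decodes the DATA segment for the common list-mode layouts: $DATATYPE F
(32-bit float), D (64-bit float) and I (unsigned integer with per-channel
bit widths that are multiples of 8).  Compensation/spillover is never
applied; files are assumed pre-processed upstream.
"""

from __future__ import annotations

import numpy as np


class FCSFormatError(ValueError):
    """Raised when a file does not conform to FCS 3.0/3.1 list mode."""


def _parse_text_segment(raw: bytes) -> dict:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Double delimiters escape a literal delimiter inside a value; splitting
    # turns each escape into an empty token which is re-joined below.
    merged = [part.decode("utf-8", errors="replace") for part in body.split(delim)]
    tokens: list[str] = []
    j = 0
    while j < len(merged):
        tok = merged[j]
        while j + 1 < len(merged) and merged[j + 1] == "" and j + 2 < len(merged):
            tok += delim.decode() + merged[j + 2]
            j += 2
        tokens.append(tok)
        j += 1
    if len(tokens) % 2 != 0:
        raise FCSFormatError("TEXT segment has an odd number of tokens")
    return {tokens[k].strip().upper(): tokens[k + 1] for k in range(0, len(tokens), 2)}


def read_fcs(path: str):
    """Read an FCS 3.0/3.1 file.

    Returns
    -------
    values : ndarray of shape (n_events, n_channels), float64
    channel_names : list of str ($PnN, falling back to $PnS)
    """
    with open(path, "rb") as fh:
        header = fh.read(58)
        if len(header) < 58:
            raise FCSFormatError("file too short for an FCS header")
        version = header[0:6].decode("ascii", errors="replace")
        if not version.startswith("FCS3"):
            raise FCSFormatError(f"unsupported FCS version {version!r}")
        try:
            text_start = int(header[10:18])
            text_end = int(header[18:26])
        except ValueError as exc:
            raise FCSFormatError("unreadable HEADER offsets") from exc
        fh.seek(text_start)
        text = _parse_text_segment(fh.read(text_end - text_start + 1))

        try:
            n_par = int(text["$PAR"])
            n_tot = int(text["$TOT"])
            datatype = text["$DATATYPE"].strip().upper()
            byteord = text["$BYTEORD"].strip()
            mode = text.get("$MODE", "L").strip().upper()
        except KeyError as exc:
            raise FCSFormatError(f"missing required keyword {exc}") from exc
        if mode != "L":
            raise FCSFormatError(f"only list mode ($MODE L) is supported, got {mode!r}")

        data_start = int(text.get("$BEGINDATA", "0") or 0)
        data_end = int(text.get("$ENDDATA", "0") or 0)
        if data_start == 0:
            try:
                data_start = int(header[26:34])
                data_end = int(header[34:42])
            except ValueError as exc:
                raise FCSFormatError("no DATA segment offsets") from exc

        names = []
        for i in range(1, n_par + 1):
            name = text.get(f"$P{i}N") or text.get(f"$P{i}S") or f"P{i}"
            names.append(name.strip())

        little = byteord.startswith("1")
        order = "<" if little else ">"
        if datatype == "F":
            dtype = np.dtype(order + "f4")
        elif datatype == "D":
            dtype = np.dtype(order + "f8")
        elif datatype == "I":
            bits = {int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
            if len(bits) != 1 or bits.pop() % 8 != 0:
                raise FCSFormatError("integer data requires a uniform byte-aligned $PnB")
            width = int(text["$P1B"]) // 8
            dtype = np.dtype(f"{order}u{width}")
        else:
            raise FCSFormatError(f"unsupported $DATATYPE {datatype!r}")

        fh.seek(data_start)
        n_bytes = data_end - data_start + 1
        raw = fh.read(n_bytes)

    needed = n_tot * n_par * dtype.itemsize
    if len(raw) < needed:
        raise FCSFormatError(
            f"DATA segment holds {len(raw)} bytes, need {needed} for "
            f"{n_tot} events x {n_par} channels"
        )
    values = np.frombuffer(raw[:needed], dtype=dtype).reshape(n_tot, n_par)
    return values.astype(np.float64), names
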