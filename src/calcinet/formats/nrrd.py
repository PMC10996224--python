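"""Tiny NRRD reader/writer covering segmentation-mask exports.

Handles raw and gzip encodings of unsigned 8/16-bit data, 2-D or 3-D with a
singleton third axis (as produced when a 2-D annotation is saved from a
volume-oriented tool).  NRRD ``sizes`` are fastest-axis-first; arrays here
are row-major (rows, cols).
"""

from __future__ import annotations

import zlib

import numpy as np

_TYPES = {
    "unsigned char": np.uint8,
    "uchar": np.uint8,
    "uint8": np.uint8,
    "uint8_t": np.uint8,
    "unsigned short": np.uint16,
    "ushort": np.uint16,
    "uint16": np.uint16,
    "uint16_t": np.uint16,
}


class NrrdFormatError(ValueError):
    pass


def write_nrrd(path, array: np.ndarray, encoding: str = "raw") -> None:
    arr = np.asarray(array)
    if arr.dtype == np.uint8:
        type_str = "unsigned char"
    elif arr.dtype == np.uint16:
        type_str = "unsigned short"
    else:
        raise NrrdFormatError(f"unsupported dtype {arr.dtype}")
    if arr.ndim not in (2, 3):
        raise NrrdFormatError("only 2-D or 3-D arrays supported")
    if encoding not in ("raw", "gzip"):
        raise NrrdFormatError(f"unsupported encoding {encoding!r}")
    sizes = " ".join(str(s) for s in arr.shape[::-1])
    header = (
        "NRRD0004\n"
        f"type: {type_str}\n"
        f"dimension: {arr.ndim}\n"
        f"sizes: {sizes}\n"
        f"encoding: {encoding}\n"
        "endian: little\n"
        "\n"
    )
    payload = arr.astype(arr.dtype.newbyteorder("<")).tobytes()
    if encoding == "gzip":
        payload = zlib.compress(payload, 9)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload)


def read_nrrd(path) -> np.ndarray:
    with open(path, "rb") as fh:
        blob = fh.read()
    if not blob.startswith(b"NRRD"):
        raise NrrdFormatError("not an NRRD file")
    header_end = blob.find(b"\n\n")
    if header_end < 0:
        raise NrrdFormatError("missing blank line terminating the header")
    fields = {}
    for line in blob[:header_end].decode("ascii", "replace").splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, _, value = line.partition(":")
        fields[key.strip().lower()] = value.lstrip(" =").strip()
    try:
        dtype = _TYPES[fields["type"]]
        sizes = [int(s) for s in fields["sizes"].split()]
        encoding = fields.get("encoding", "raw")
    except KeyError as exc:
        raise NrrdFormatError(f"missing header field {exc}") from exc
    if encoding.startswith("gz"):
        data = zlib.decompress(blob[header_end + 2 :])
    elif encoding == "raw":
        data = blob[header_end + 2 :]
    else:
        raise NrrdFormatError(f"unsupported encoding {encoding!r}")
    n = int(np.prod(sizes))
    arr = np.frombuffer(data, dtype=np.dtype(dtype).newbyteorder("<"), count=n)
    return arr.reshape(sizes[::-1]).copy()
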