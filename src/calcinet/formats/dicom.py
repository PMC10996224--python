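"""Minimal single-frame grayscale DICOM codec (Explicit VR Little Endian).

Supports exactly the dialect this package writes — unsigned 16-bit
MONOCHROME1/MONOCHROME2 secondary-capture images with an optional VOI LUT
sequence — plus enough generality to skip unknown elements.  Compressed
transfer syntaxes and color photometric interpretations are rejected as
dialect errors, not corruption.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

TRANSFER_SYNTAX_EXPLICIT_LE = "1.2.840.10008.1.2.1"
SOP_CLASS_SECONDARY_CAPTURE = "1.2.840.10008.5.1.4.1.1.7"
_IMPLEMENTATION_UID = "1.2.826.0.1.3680043.10.1462.1"
_UID_ROOT = "1.2.826.0.1.3680043.10.1462.2."

_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}


class DicomFormatError(ValueError):
    """Unsupported DICOM dialect (transfer syntax, photometric, VR...)."""


@dataclass
class VoiLut:
    """A monotone stored-value -> output mapping from a VOI LUT item."""

    first_value: int
    table: np.ndarray  # uint16

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=np.uint16)
        if self.table.ndim != 1 or self.table.size == 0:
            raise DicomFormatError("LUT table must be a non-empty vector")
        if np.any(np.diff(self.table.astype(np.int64)) < 0):
            raise DicomFormatError("LUT table is not monotone non-decreasing")

    def apply(self, x: np.ndarray) -> np.ndarray:
        idx = np.clip(x.astype(np.int64) - self.first_value, 0, self.table.size - 1)
        return self.table[idx]


@dataclass
class DicomImage:
    pixels: np.ndarray  # uint16, (rows, cols), raw stored values
    photometric: str
    bits_stored: int
    luts: List[VoiLut]


def _pad(value: bytes, pad_byte: bytes = b"\x00") -> bytes:
    return value + pad_byte if len(value) % 2 else value


def _elem(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    value = _pad(value, b" " if vr in (b"UI", b"CS", b"SH", b"LO") else b"\x00")
    if vr == b"UI":
        value = value[:-1] + b"\x00" if value.endswith(b" ") else value
    head = struct.pack("<HH", group, elem) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + struct.pack("<H", len(value)) + value


def _us(*vals: int) -> bytes:
    return struct.pack(f"<{len(vals)}H", *vals)


def _encode_lut_sequence(luts: List[VoiLut]) -> bytes:
    items = b""
    for lut in luts:
        n = lut.table.size
        desc = _us(0 if n == 65536 else n, lut.first_value, 16)
        body = _elem(0x0028, 0x3002, b"US", desc)
        body += _elem(0x0028, 0x3006, b"OW", lut.table.astype("<u2").tobytes())
        items += struct.pack("<HH", 0xFFFE, 0xE000) + struct.pack("<I", len(body)) + body
    return items


def write_dicom(
    path,
    pixels: np.ndarray,
    photometric: str = "MONOCHROME2",
    luts: Optional[List[VoiLut]] = None,
    bits_stored: int = 16,
    instance_number: int = 1,
) -> None:
    """Write a single-frame unsigned grayscale image, deterministically."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError("pixels must be a 2-D array")
    if arr.dtype != np.uint16:
        if np.any(arr < 0) or np.any(arr > 65535):
            raise ValueError("pixel values outside uint16 range")
        arr = arr.astype(np.uint16)
    if photometric not in ("MONOCHROME1", "MONOCHROME2"):
        raise DicomFormatError(f"unsupported photometric {photometric!r}")
    rows, cols = arr.shape
    # deterministic instance UID: derived from shape + a stable content digest
    digest = int(np.uint64(np.sum(arr.astype(np.uint64) * 2654435761) % 10**12))
    sop_uid = f"{_UID_ROOT}{rows}.{cols}.{digest}.{instance_number}"

    ds = b""
    ds += _elem(0x0008, 0x0016, b"UI", SOP_CLASS_SECONDARY_CAPTURE.encode())
    ds += _elem(0x0008, 0x0018, b"UI", sop_uid.encode())
    ds += _elem(0x0028, 0x0002, b"US", _us(1))
    ds += _elem(0x0028, 0x0004, b"CS", photometric.encode())
    ds += _elem(0x0028, 0x0010, b"US", _us(rows))
    ds += _elem(0x0028, 0x0011, b"US", _us(cols))
    ds += _elem(0x0028, 0x0100, b"US", _us(16))
    ds += _elem(0x0028, 0x0101, b"US", _us(bits_stored))
    ds += _elem(0x0028, 0x0102, b"US", _us(bits_stored - 1))
    ds += _elem(0x0028, 0x0103, b"US", _us(0))
    if luts:
        ds += _elem(0x0028, 0x3010, b"SQ", _encode_lut_sequence(list(luts)))
    ds += _elem(0x7FE0, 0x0010, b"OW", arr.astype("<u2").tobytes())

    meta = b""
    meta += _elem(0x0002, 0x0001, b"OB", b"\x00\x01")
    meta += _elem(0x0002, 0x0002, b"UI", SOP_CLASS_SECONDARY_CAPTURE.encode())
    meta += _elem(0x0002, 0x0003, b"UI", sop_uid.encode())
    meta += _elem(0x0002, 0x0010, b"UI", TRANSFER_SYNTAX_EXPLICIT_LE.encode())
    meta += _elem(0x0002, 0x0012, b"UI", _IMPLEMENTATION_UID.encode())
    group_len = _elem(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta)))

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM")
        fh.write(group_len + meta)
        fh.write(ds)


class _Reader:
    def __init__(self, buf: bytes):
        self.buf = buf
        self.pos = 0

    def u16(self):
        v = struct.unpack_from("<H", self.buf, self.pos)[0]
        self.pos += 2
        return v

    def u32(self):
        v = struct.unpack_from("<I", self.buf, self.pos)[0]
        self.pos += 4
        return v

    def raw(self, n):
        v = self.buf[self.pos : self.pos + n]
        self.pos += n
        return v

    def eof(self):
        return self.pos >= len(self.buf)


def _read_element(r: _Reader):
    group, elem = r.u16(), r.u16()
    if group == 0xFFFE:  # item / delimiter — implicit structure, no VR
        length = r.u32()
        return (group, elem), b"", length, None
    vr = r.raw(2)
    if vr in _LONG_VRS:
        r.raw(2)
        length = r.u32()
    else:
        length = r.u16()
    return (group, elem), vr, length, None


def _parse_dataset(r: _Reader, end: int, out: dict, prefix: Tuple = ()):
    while r.pos < end and not r.eof():
        (group, elem), vr, length, _ = _read_element(r)
        tag = (group, elem)
        if tag == (0xFFFE, 0xE00D) or tag == (0xFFFE, 0xE0DD):
            continue
        if vr == b"SQ" or (tag != (0xFFFE, 0xE000) and length == 0xFFFFFFFF):
            items = _parse_sequence(r, length)
            out[prefix + tag] = items
            continue
        if length == 0xFFFFFFFF:
            raise DicomFormatError("undefined length outside a sequence")
        out[prefix + tag] = (vr, r.raw(length))


def _parse_sequence(r: _Reader, length: int):
    end = len(r.buf) if length == 0xFFFFFFFF else r.pos + length
    items = []
    while r.pos < end and not r.eof():
        (group, elem), _, ilen, _ = _read_element(r)
        if (group, elem) == (0xFFFE, 0xE0DD):
            break
        if (group, elem) != (0xFFFE, 0xE000):
            raise DicomFormatError("malformed sequence item")
        item: dict = {}
        iend = len(r.buf) if ilen == 0xFFFFFFFF else r.pos + ilen
        _parse_dataset(r, iend, item)
        items.append(item)
        if ilen == 0xFFFFFFFF:
            # _parse_dataset stops at the item delimiter it consumed
            pass
    return items


def _decode_str(v: bytes) -> str:
    return v.decode("ascii", "replace").strip("\x00 ").strip()


def read_dicom(path) -> DicomImage:
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise DicomFormatError("missing DICM preamble marker")
    r = _Reader(buf)
    r.pos = 132
    elems: dict = {}
    _parse_dataset(r, len(buf), elems)

    ts = elems.get((0x0002, 0x0010))
    if ts is not None and _decode_str(ts[1]) != TRANSFER_SYNTAX_EXPLICIT_LE:
        raise DicomFormatError(f"unsupported transfer syntax {_decode_str(ts[1])!r}")
    photometric = _decode_str(elems[(0x0028, 0x0004)][1])
    if photometric not in ("MONOCHROME1", "MONOCHROME2"):
        raise DicomFormatError(f"unsupported photometric interpretation {photometric!r}")
    rows = struct.unpack("<H", elems[(0x0028, 0x0010)][1])[0]
    cols = struct.unpack("<H", elems[(0x0028, 0x0011)][1])[0]
    bits_alloc = struct.unpack("<H", elems[(0x0028, 0x0100)][1])[0]
    bits_stored = struct.unpack("<H", elems[(0x0028, 0x0101)][1])[0]
    if bits_alloc != 16:
        raise DicomFormatError(f"unsupported bits allocated {bits_alloc}")
    pixel_rep = struct.unpack("<H", elems.get((0x0028, 0x0103), (b"US", b"\x00\x00"))[1])[0]
    if pixel_rep != 0:
        raise DicomFormatError("signed pixel data is not supported")
    raw = elems[(0x7FE0, 0x0010)][1]
    pixels = np.frombuffer(raw, dtype="<u2", count=rows * cols).reshape(rows, cols).copy()

    luts: List[VoiLut] = []
    for item in elems.get((0x0028, 0x3010), []):
        desc = np.frombuffer(item[(0x0028, 0x3002)][1], dtype="<u2")
        n = int(desc[0]) or 65536
        first = int(desc[1])
        table = np.frombuffer(item[(0x0028, 0x3006)][1], dtype="<u2", count=n)
        luts.append(VoiLut(first_value=first, table=table))

    return DicomImage(pixels=pixels, photometric=photometric, bits_stored=bits_stored, luts=luts)
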