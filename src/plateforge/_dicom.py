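"""Minimal DICOM series reader/writer (explicit VR little endian only).

Supports exactly the subset needed to ingest uncompressed single-frame CT
slices and to emit synthetic test series. Real-world DICOM variability
(implicit VR, compressed transfer syntaxes, multiframe) is out of scope;
unsupported files raise a clear error.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

TRANSFER_SYNTAX_EXPLICIT_LE = "1.2.840.10008.1.2.1"

# VRs with a 2-byte reserved field and 4-byte length
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

TAG_ROWS = (0x0028, 0x0010)
TAG_COLS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_IPP = (0x0020, 0x0032)
TAG_IOP = (0x0020, 0x0037)
TAG_SLOPE = (0x0028, 0x1053)
TAG_INTERCEPT = (0x0028, 0x1052)
TAG_BITS_ALLOC = (0x0028, 0x0100)
TAG_PIXEL_REP = (0x0028, 0x0103)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)
TAG_INSTANCE = (0x0020, 0x0013)


class DicomError(ValueError):
    pass


def read_slice(path) -> dict:
    """Parse one explicit-VR-LE part-10 file into a tag -> value dict."""
    raw = Path(path).read_bytes()
    if len(raw) < 132 or raw[128:132] != b"DICM":
        raise DicomError(f"{path}: missing DICM magic")
    pos = 132
    elements: dict = {}
    n = len(raw)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", raw, pos)
        vr = raw[pos + 4:pos + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", raw, pos + 8)
            val_off = pos + 12
        elif vr.isalpha() and vr.isupper():
            (length,) = struct.unpack_from("<H", raw, pos + 6)
            val_off = pos + 8
        else:
            raise DicomError(
                f"{path}: implicit VR or corrupt element at offset {pos}; "
                "only explicit VR little endian is supported")
        if length == 0xFFFFFFFF:
            raise DicomError(f"{path}: undefined-length element unsupported")
        value = raw[val_off:val_off + length]
        elements[(group, elem)] = (vr, value)
        pos = val_off + length
    out: dict = {}
    for tag, (vr, value) in elements.items():
        if vr == b"US":
            out[tag] = struct.unpack("<H", value[:2])[0]
        elif vr == b"DS":
            txt = value.decode("ascii").strip("\x00 ")
            out[tag] = [float(x) for x in txt.split("\\")] if txt else []
        elif vr == b"IS":
            txt = value.decode("ascii").strip("\x00 ")
            out[tag] = int(txt) if txt else 0
        elif vr in (b"OW", b"OB"):
            out[tag] = value
        else:
            out[tag] = value
    return out


def read_series(directory):
    """Read all ``.dcm`` files in a directory into (array, spacing, origin).

    Returns intensities shaped (nx, ny, nz) with rescale slope/intercept
    applied, spacing (sx, sy, sz) mm and origin mm. Slices are sorted along
    z by ImagePositionPatient; a non-uniform z step raises ``DicomError``
    naming the offending slices.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise DicomError(f"no .dcm files in {directory}")
    slices = []
    for f in files:
        el = read_slice(f)
        for tag, name in [(TAG_ROWS, "Rows"), (TAG_COLS, "Columns"),
                          (TAG_PIXEL_SPACING, "PixelSpacing"),
                          (TAG_IPP, "ImagePositionPatient"),
                          (TAG_PIXEL_DATA, "PixelData")]:
            if tag not in el:
                raise DicomError(f"{f}: missing required tag {name}")
        slices.append((f, el))
    slices.sort(key=lambda fe: fe[1][TAG_IPP][2])
    zs = np.array([el[TAG_IPP][2] for _, el in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.any(dz <= 0):
            raise DicomError("duplicate or non-increasing slice positions")
        if np.max(dz) - np.min(dz) > 1e-3:
            bad = [str(slices[i + 1][0].name)
                   for i in np.nonzero(np.abs(dz - np.median(dz)) > 1e-3)[0]]
            raise DicomError(f"non-uniform slice spacing at: {', '.join(bad)}")
        sz = float(np.median(dz))
    else:
        sz = 1.0
    _, el0 = slices[0]
    rows, cols = el0[TAG_ROWS], el0[TAG_COLS]
    sy, sx = el0[TAG_PIXEL_SPACING]  # PixelSpacing is (row, col) spacing
    slope = el0.get(TAG_SLOPE, [1.0])[0] if TAG_SLOPE in el0 else 1.0
    intercept = el0.get(TAG_INTERCEPT, [0.0])[0] if TAG_INTERCEPT in el0 else 0.0
    signed = el0.get(TAG_PIXEL_REP, 0) == 1
    bits = el0.get(TAG_BITS_ALLOC, 16)
    if bits != 16:
        raise DicomError(f"unsupported BitsAllocated {bits}")
    dtype = np.dtype("<i2") if signed else np.dtype("<u2")
    planes = []
    for f, el in slices:
        px = np.frombuffer(el[TAG_PIXEL_DATA], dtype=dtype,
                           count=rows * cols).reshape(rows, cols)
        planes.append(px.astype(np.float64) * slope + intercept)
    # plane index [row, col] = [y, x]; assemble as (x, y, z)
    arr = np.stack(planes, axis=-1).transpose(1, 0, 2)
    origin = np.array([el0[TAG_IPP][0], el0[TAG_IPP][1], zs[0]])
    return arr, np.array([sx, sy, sz], dtype=float), origin


def _element(group, elem, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in (b"OB",) else b" "
    if vr in _LONG_VRS:
        return struct.pack("<HH2sHI", group, elem, vr, 0, len(value)) + value
    return struct.pack("<HH2sH", group, elem, vr, len(value)) + value


def write_slice(path, pixels: np.ndarray, pixel_spacing, position,
                slope: float = 1.0, intercept: float = 0.0,
                instance_number: int = 1) -> None:
    """Write a minimal synthetic CT slice (int16, explicit VR LE)."""
    pixels = np.ascontiguousarray(pixels, dtype="<i2")
    rows, cols = pixels.shape

    def ds(values) -> bytes:
        return "\\".join(f"{v:.6f}" for v in values).encode()

    meta = _element(0x0002, 0x0010, b"UI", TRANSFER_SYNTAX_EXPLICIT_LE.encode())
    group_len = _element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta)))
    body = b"".join([
        _element(*TAG_IPP, b"DS", ds(position)),
        _element(*TAG_IOP, b"DS", ds([1, 0, 0, 0, 1, 0])),
        _element(*TAG_INSTANCE, b"IS", str(instance_number).encode()),
        _element(*TAG_ROWS, b"US", struct.pack("<H", rows)),
        _element(*TAG_COLS, b"US", struct.pack("<H", cols)),
        _element(*TAG_PIXEL_SPACING, b"DS", ds(pixel_spacing)),
        _element(*TAG_BITS_ALLOC, b"US", struct.pack("<H", 16)),
        _element(*TAG_PIXEL_REP, b"US", struct.pack("<H", 1)),
        _element(*TAG_INTERCEPT, b"DS", ds([intercept])),
        _element(*TAG_SLOPE, b"DS", ds([slope])),
        _element(*TAG_PIXEL_DATA, b"OW", pixels.tobytes()),
    ])
    Path(path).write_bytes(b"\x00" * 128 + b"DICM" + group_len + meta + body)
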