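"""Minimal DICOM CT series I/O (Explicit VR Little Endian, uncompressed).

Supports exactly what the voxelization path needs from single-frame CT
series: geometry tags, rescale slope/intercept and 16-bit pixel data.  The
paired writer exists so synthetic series can be generated for tests and
demos without external imaging data.  Not a general DICOM implementation.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .spectrum import ConfigurationError

__all__ = ["SliceInfo", "read_slice", "read_series", "write_slice", "write_series"]

_EXPLICIT_LE = "1.2.840.10008.1.2.1"
_CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"
_IMPL_UID = "1.2.826.0.1.3680043.8.498.1"

# VRs carrying a 2-byte reserved field and 4-byte length
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

TAGS = {
    "sop_class": (0x0008, 0x0016),
    "sop_instance": (0x0008, 0x0018),
    "modality": (0x0008, 0x0060),
    "slice_thickness": (0x0018, 0x0050),
    "study_uid": (0x0020, 0x000D),
    "series_uid": (0x0020, 0x000E),
    "instance_number": (0x0020, 0x0013),
    "image_position": (0x0020, 0x0032),
    "image_orientation": (0x0020, 0x0037),
    "samples_per_pixel": (0x0028, 0x0002),
    "photometric": (0x0028, 0x0004),
    "rows": (0x0028, 0x0010),
    "columns": (0x0028, 0x0011),
    "pixel_spacing": (0x0028, 0x0030),
    "bits_allocated": (0x0028, 0x0100),
    "bits_stored": (0x0028, 0x0101),
    "high_bit": (0x0028, 0x0102),
    "pixel_representation": (0x0028, 0x0103),
    "rescale_intercept": (0x0028, 0x1052),
    "rescale_slope": (0x0028, 0x1053),
    "pixel_data": (0x7FE0, 0x0010),
}


@dataclass
class SliceInfo:
    """One parsed CT slice."""

    raw: np.ndarray  # (rows, cols) stored pixel values
    position_mm: tuple[float, float, float]
    orientation: tuple[float, ...]
    pixel_spacing_mm: tuple[float, float]  # (row spacing, column spacing)
    slice_thickness_mm: float
    rescale_slope: float
    rescale_intercept: float
    instance_number: int

    @property
    def hu(self) -> np.ndarray:
        return self.rescale_slope * self.raw.astype(np.float64) + self.rescale_intercept


def _encode_element(group, element, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b" " if vr not in (b"OB", b"OW") else b"\x00"
    head = struct.pack("<HH", group, element) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + struct.pack("<H", len(value)) + value


def _ds(*values) -> bytes:
    return "\\".join(f"{v:.10g}" for v in values).encode()


def write_slice(
    path,
    raw: np.ndarray,
    position_mm,
    pixel_spacing_mm,
    slice_thickness_mm=1.0,
    rescale_slope=1.0,
    rescale_intercept=0.0,
    instance_number=1,
    series_uid="1.2.826.0.1.3680043.8.498.100",
    study_uid="1.2.826.0.1.3680043.8.498.10",
) -> None:
    """Write a single int16 CT slice as Explicit VR Little Endian."""
    raw = np.ascontiguousarray(raw, dtype=np.int16)
    if raw.ndim != 2:
        raise ConfigurationError("slice pixel array must be 2-D")
    sop_uid = f"{series_uid}.{instance_number}"

    meta = b"".join(
        [
            _encode_element(0x0002, 0x0001, b"OB", b"\x00\x01"),
            _encode_element(0x0002, 0x0002, b"UI", _CT_SOP_CLASS.encode()),
            _encode_element(0x0002, 0x0003, b"UI", sop_uid.encode()),
            _encode_element(0x0002, 0x0010, b"UI", _EXPLICIT_LE.encode()),
            _encode_element(0x0002, 0x0012, b"UI", _IMPL_UID.encode()),
        ]
    )
    rows, cols = raw.shape
    body = b"".join(
        [
            _encode_element(0x0008, 0x0016, b"UI", _CT_SOP_CLASS.encode()),
            _encode_element(0x0008, 0x0018, b"UI", sop_uid.encode()),
            _encode_element(0x0008, 0x0060, b"CS", b"CT"),
            _encode_element(0x0018, 0x0050, b"DS", _ds(slice_thickness_mm)),
            _encode_element(0x0020, 0x000D, b"UI", study_uid.encode()),
            _encode_element(0x0020, 0x000E, b"UI", series_uid.encode()),
            _encode_element(0x0020, 0x0013, b"IS", str(instance_number).encode()),
            _encode_element(0x0020, 0x0032, b"DS", _ds(*position_mm)),
            _encode_element(0x0020, 0x0037, b"DS", _ds(1, 0, 0, 0, 1, 0)),
            _encode_element(0x0028, 0x0002, b"US", struct.pack("<H", 1)),
            _encode_element(0x0028, 0x0004, b"CS", b"MONOCHROME2"),
            _encode_element(0x0028, 0x0010, b"US", struct.pack("<H", rows)),
            _encode_element(0x0028, 0x0011, b"US", struct.pack("<H", cols)),
            _encode_element(0x0028, 0x0030, b"DS", _ds(*pixel_spacing_mm)),
            _encode_element(0x0028, 0x0100, b"US", struct.pack("<H", 16)),
            _encode_element(0x0028, 0x0101, b"US", struct.pack("<H", 16)),
            _encode_element(0x0028, 0x0102, b"US", struct.pack("<H", 15)),
            _encode_element(0x0028, 0x0103, b"US", struct.pack("<H", 1)),
            _encode_element(0x0028, 0x1052, b"DS", _ds(rescale_intercept)),
            _encode_element(0x0028, 0x1053, b"DS", _ds(rescale_slope)),
            _encode_element(0x7FE0, 0x0010, b"OW", raw.tobytes()),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM")
        fh.write(_encode_element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta))))
        fh.write(meta)
        fh.write(body)


def _parse_elements(buf: bytes, offset: int):
    """Yield (tag, vr, value-bytes) from an Explicit VR LE byte stream."""
    n = len(buf)
    while offset + 8 <= n:
        group, element = struct.unpack_from("<HH", buf, offset)
        vr = buf[offset + 4 : offset + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, offset + 8)
            start = offset + 12
        else:
            (length,) = struct.unpack_from("<H", buf, offset + 6)
            start = offset + 8
        if length == 0xFFFFFFFF:
            raise ConfigurationError("undefined-length elements are not supported")
        value = buf[start : start + length]
        yield (group, element), vr, value, start + length
        offset = start + length


def read_slice(path) -> SliceInfo:
    buf = Path(path).read_bytes()
    if buf[128:132] != b"DICM":
        raise ConfigurationError(f"{path}: not a DICOM part-10 file")
    elements = {}
    transfer_syntax = None
    for tag, vr, value, end in _parse_elements(buf, 132):
        if tag == (0x0002, 0x0010):
            transfer_syntax = value.decode().strip("\x00 ")
        if tag[0] != 0x0002 and transfer_syntax not in (None, _EXPLICIT_LE):
            raise ConfigurationError(
                f"unsupported transfer syntax {transfer_syntax!r}; only Explicit "
                "VR Little Endian is handled"
            )
        elements[tag] = (vr, value)

    def get(name, default=None):
        item = elements.get(TAGS[name])
        if item is None:
            if default is not None:
                return default
            raise ConfigurationError(f"{path}: missing required tag {name}")
        return item

    def decode_ds(name, default=None):
        item = elements.get(TAGS[name])
        if item is None:
            return default
        return tuple(float(v) for v in item[1].decode().strip("\x00 ").split("\\"))

    def decode_us(name):
        return struct.unpack("<H", get(name)[1][:2])[0]

    rows, cols = decode_us("rows"), decode_us("columns")
    bits = decode_us("bits_allocated")
    if bits != 16:
        raise ConfigurationError("only 16-bit pixel data is supported")
    signed = decode_us("pixel_representation") == 1
    dtype = np.int16 if signed else np.uint16
    raw = np.frombuffer(get("pixel_data")[1][: rows * cols * 2], dtype=dtype)
    raw = raw.reshape(rows, cols)
    instance = int(get("instance_number", (b"IS", b"1"))[1].decode().strip("\x00 ") or 1)
    return SliceInfo(
        raw=raw,
        position_mm=decode_ds("image_position"),
        orientation=decode_ds("image_orientation", (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)),
        pixel_spacing_mm=decode_ds("pixel_spacing"),
        slice_thickness_mm=decode_ds("slice_thickness", (1.0,))[0],
        rescale_slope=decode_ds("rescale_slope", (1.0,))[0],
        rescale_intercept=decode_ds("rescale_intercept", (0.0,))[0],
        instance_number=instance,
    )


def read_series(directory) -> list[SliceInfo]:
    """Read and geometry-validate all ``.dcm`` slices in a directory,
    returned sorted by z position."""
    paths = sorted(Path(directory).glob("*.dcm"))
    if not paths:
        raise ConfigurationError(f"no .dcm files under {directory}")
    slices = [read_slice(p) for p in paths]
    slices.sort(key=lambda s: s.position_mm[2])
    first = slices[0]
    for s in slices[1:]:
        if s.raw.shape != first.raw.shape:
            raise ConfigurationError("inconsistent slice dimensions in series")
        if not np.allclose(s.pixel_spacing_mm, first.pixel_spacing_mm):
            raise ConfigurationError("inconsistent pixel spacing in series")
        if not np.allclose(s.orientation, first.orientation):
            raise ConfigurationError("inconsistent orientation in series")
    if not np.allclose(first.orientation, (1, 0, 0, 0, 1, 0)):
        raise ConfigurationError("only axis-aligned (identity) orientation is supported")
    if len(slices) > 1:
        gaps = np.diff([s.position_mm[2] for s in slices])
        if np.ptp(gaps) > 1e-6:
            raise ConfigurationError("non-uniform slice spacing in series")
    return slices


def write_series(
    directory,
    hu: np.ndarray,
    spacing_mm,
    origin_mm=(0.0, 0.0, 0.0),
    rescale_slope=1.0,
    rescale_intercept=-1024.0,
) -> None:
    """Write an (nx, ny, nz) HU grid as one DICOM file per z slice."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hu = np.asarray(hu)
    raw = np.rint((hu - rescale_intercept) / rescale_slope).astype(np.int16)
    sx, sy, sz = spacing_mm
    for k in range(hu.shape[2]):
        write_slice(
            directory / f"slice_{k:04d}.dcm",
            raw[:, :, k].T,  # rows = y, columns = x
            position_mm=(origin_mm[0], origin_mm[1], origin_mm[2] + k * sz),
            pixel_spacing_mm=(sy, sx),
            slice_thickness_mm=sz,
            rescale_slope=rescale_slope,
            rescale_intercept=rescale_intercept,
            instance_number=k + 1,
        )
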