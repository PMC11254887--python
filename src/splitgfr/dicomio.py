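"""Minimal DICOM I/O for dynamic NM series (explicit VR little endian only).

Supports exactly what the pipeline needs: writing phantom scans as a
multi-frame NM object (or a directory of per-frame files) and reading them
back with frame ordering restored from acquisition-time tags.  This is a
deliberately small, self-contained subset — not a general DICOM
implementation.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .core import AcquisitionMeta, DynamicRenogram, PatientInfo

__all__ = [
    "write_dynamic_dicom",
    "read_dynamic_dicom",
    "frame_count_ok",
    "MissingAnthropometricsError",
]

_TRANSFER_SYNTAX = "1.2.840.10008.1.2.1"  # explicit VR little endian
_NM_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.20"
_UID_ROOT = "1.2.826.0.1.3680043.8.498"
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

TAG_SEX = (0x0010, 0x0040)
TAG_AGE = (0x0010, 0x1010)
TAG_SIZE = (0x0010, 0x1020)
TAG_WEIGHT = (0x0010, 0x1030)
TAG_ACQ_TIME = (0x0008, 0x0032)
TAG_MODALITY = (0x0008, 0x0060)
TAG_FRAME_TIME = (0x0018, 0x1063)
TAG_INSTANCE = (0x0020, 0x0013)
TAG_NFRAMES = (0x0028, 0x0008)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLS = (0x0028, 0x0011)
TAG_PIXELDATA = (0x7FE0, 0x0010)
TAG_PRIVATE_CREATOR = (0x0009, 0x0010)
TAG_PRIVATE_META = (0x0009, 0x1001)


class MissingAnthropometricsError(ValueError):
    """Patient height or weight absent: the depth formulas cannot run."""


def _pad(value: bytes, pad_byte: bytes = b" ") -> bytes:
    return value + pad_byte if len(value) % 2 else value


def _element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    value = _pad(value, b"\x00" if vr in (b"UI", b"OB", b"OW", b"UT") else b" ")
    if vr in _LONG_VRS:
        return struct.pack("<HH2sHI", group, elem, vr, 0, len(value)) + value
    return struct.pack("<HH2sH", group, elem, vr, len(value)) + value


def _str_elem(group, elem, vr: bytes, text: str) -> bytes:
    return _element(group, elem, vr, text.encode("ascii"))


def _us(group, elem, value: int) -> bytes:
    return _element(group, elem, b"US", struct.pack("<H", value))


def _dataset_bytes(scan: DynamicRenogram, frame: int | None, uid_suffix: str) -> bytes:
    meta, patient = scan.meta, scan.patient
    if frame is None:
        pix = np.rint(np.asarray(scan.counts)).astype("<u2")
        n_frames = scan.n_frames
        t_acq = 0.0
        instance = 1
    else:
        pix = np.rint(np.asarray(scan.counts[frame])).astype("<u2")
        n_frames = 1
        t_acq = frame * meta.frame_duration_s
        instance = frame + 1
    if np.any(np.asarray(scan.counts) > 65535):
        raise ValueError("counts exceed 16-bit pixel range")

    hh = int(t_acq // 3600) % 24
    mm = int(t_acq % 3600) // 60
    ss = t_acq % 60
    acq_time = f"{hh:02d}{mm:02d}{ss:09.6f}"

    extras = {
        "zoom": meta.zoom,
        "injected_activity_MBq": meta.injected_activity_MBq,
        "syringe_pre_counts": meta.syringe_pre_counts,
        "syringe_post_counts": meta.syringe_post_counts,
        "t_pre": meta.t_pre,
        "t_post": meta.t_post,
        "t_inj": meta.t_inj,
        "scan_id": scan.scan_id,
    }

    out = b"".join(
        [
            _str_elem(0x0008, 0x0016, b"UI", _NM_SOP_CLASS),
            _str_elem(0x0008, 0x0018, b"UI", f"{_UID_ROOT}.{uid_suffix}"),
            _str_elem(*TAG_ACQ_TIME, b"TM", acq_time),
            _str_elem(*TAG_MODALITY, b"CS", "NM"),
            _str_elem(*TAG_SEX, b"CS", "M" if patient.sex == "male" else "F"),
            _str_elem(*TAG_AGE, b"AS", f"{patient.age:03d}Y"),
            _str_elem(*TAG_SIZE, b"DS", f"{patient.height_cm / 100.0:.4f}"),
            _str_elem(*TAG_WEIGHT, b"DS", f"{patient.weight_kg:.2f}"),
            _str_elem(*TAG_FRAME_TIME, b"DS", f"{meta.frame_duration_s * 1000.0:.1f}"),
            _str_elem(*TAG_INSTANCE, b"IS", str(instance)),
            _us(0x0028, 0x0002, 1),
            _str_elem(0x0028, 0x0004, b"CS", "MONOCHROME2"),
            _str_elem(*TAG_NFRAMES, b"IS", str(n_frames)),
            _us(*TAG_ROWS, pix.shape[-2]),
            _us(*TAG_COLS, pix.shape[-1]),
            _us(0x0028, 0x0100, 16),
            _us(0x0028, 0x0101, 16),
            _us(0x0028, 0x0102, 15),
            _us(0x0028, 0x0103, 0),
            _str_elem(*TAG_PRIVATE_CREATOR, b"LO", "SPLITGFR"),
            _element(*TAG_PRIVATE_META, b"UT", json.dumps(extras).encode("ascii")),
            _element(*TAG_PIXELDATA, b"OW", pix.tobytes()),
        ]
    )
    return out


def _file_bytes(dataset: bytes, uid_suffix: str) -> bytes:
    meta_elems = b"".join(
        [
            _element(0x0002, 0x0001, b"OB", b"\x00\x01"),
            _str_elem(0x0002, 0x0002, b"UI", _NM_SOP_CLASS),
            _str_elem(0x0002, 0x0003, b"UI", f"{_UID_ROOT}.{uid_suffix}"),
            _str_elem(0x0002, 0x0010, b"UI", _TRANSFER_SYNTAX),
            _str_elem(0x0002, 0x0012, b"UI", f"{_UID_ROOT}.1"),
        ]
    )
    group_len = _element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta_elems)))
    return b"\x00" * 128 + b"DICM" + group_len + meta_elems + dataset


def write_dynamic_dicom(path, scan: DynamicRenogram, multiframe: bool = True) -> Path:
    """Write a scan as one multi-frame NM file, or (``multiframe=False``) a
    directory of single-frame files."""
    path = Path(path)
    if multiframe:
        suffix = f"{abs(hash(scan.scan_id)) % 10**8}.0"
        path.write_bytes(_file_bytes(_dataset_bytes(scan, None, suffix), suffix))
        return path
    path.mkdir(parents=True, exist_ok=True)
    for f in range(scan.n_frames):
        suffix = f"{abs(hash(scan.scan_id)) % 10**8}.{f + 1}"
        out = path / f"frame{f + 1:03d}.dcm"
        out.write_bytes(_file_bytes(_dataset_bytes(scan, f, suffix), suffix))
    return path


# ---------------------------------------------------------------------------
# reading


def _parse_elements(buf: bytes, start: int) -> dict[tuple[int, int], tuple[bytes, bytes]]:
    elements = {}
    pos = start
    n = len(buf)
    while pos + 8 <= n:
        group, elem, vr = struct.unpack("<HH2s", buf[pos : pos + 6])
        if vr in _LONG_VRS:
            (length,) = struct.unpack("<I", buf[pos + 8 : pos + 12])
            value_start = pos + 12
        else:
            (length,) = struct.unpack("<H", buf[pos + 6 : pos + 8])
            value_start = pos + 8
        elements[(group, elem)] = (vr, buf[value_start : value_start + length])
        pos = value_start + length
    return elements


def _read_file(path: Path) -> dict[tuple[int, int], tuple[bytes, bytes]]:
    buf = path.read_bytes()
    if buf[128:132] != b"DICM":
        raise ValueError(f"{path} is not a DICOM file")
    return _parse_elements(buf, 132)


def _text(elements, tag) -> str | None:
    if tag not in elements:
        return None
    return elements[tag][1].decode("ascii").strip("\x00 ").strip()


def _assemble(elements, frames: np.ndarray, path_label: str) -> DynamicRenogram:
    sex_code = _text(elements, TAG_SEX)
    age_str = _text(elements, TAG_AGE) or "0Y"
    height_m = _text(elements, TAG_SIZE)
    weight = _text(elements, TAG_WEIGHT)
    if not height_m or not weight:
        raise MissingAnthropometricsError(
            f"{path_label}: patient height/weight missing; depth formulas need them"
        )
    patient = PatientInfo(
        age=int(age_str.rstrip("YMWD")),
        sex="male" if sex_code == "M" else "female",
        weight_kg=float(weight),
        height_cm=float(height_m) * 100.0,
    )
    extras = json.loads(_text(elements, TAG_PRIVATE_META) or "{}")
    frame_time_ms = float(_text(elements, TAG_FRAME_TIME) or "15000")
    meta = AcquisitionMeta(
        frame_duration_s=frame_time_ms / 1000.0,
        n_frames=frames.shape[0],
        matrix_size=frames.shape[1],
        zoom=extras.get("zoom", 1.45),
        injected_activity_MBq=extras.get("injected_activity_MBq", 185.0),
        syringe_pre_counts=extras.get("syringe_pre_counts", 0.0),
        syringe_post_counts=extras.get("syringe_post_counts", 0.0),
        t_pre=extras.get("t_pre", 0.0),
        t_post=extras.get("t_post", 0.0),
        t_inj=extras.get("t_inj", 0.0),
    )
    return DynamicRenogram(
        counts=frames.astype(np.int64),
        meta=meta,
        patient=patient,
        scan_id=extras.get("scan_id", path_label),
    )


def _frames_from(elements) -> np.ndarray:
    rows = struct.unpack("<H", elements[TAG_ROWS][1][:2])[0]
    cols = struct.unpack("<H", elements[TAG_COLS][1][:2])[0]
    n = int(_text(elements, TAG_NFRAMES) or "1")
    pix = np.frombuffer(elements[TAG_PIXELDATA][1], dtype="<u2")
    return pix.reshape(n, rows, cols)


def read_dynamic_dicom(path) -> DynamicRenogram:
    """Read a multi-frame NM file or a directory of per-frame files.

    Directory frames are re-ordered by their acquisition-time tag, so shuffled
    filenames round-trip correctly.  Raises
    :class:`MissingAnthropometricsError` when height/weight are absent.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.dcm"))
        if not files:
            raise ValueError(f"no DICOM files in {path}")
        parsed = [_read_file(f) for f in files]

        def sort_key(elements):
            t = _text(elements, TAG_ACQ_TIME) or "000000"
            inst = int(_text(elements, TAG_INSTANCE) or "0")
            return (t, inst)

        parsed.sort(key=sort_key)
        frames = np.concatenate([_frames_from(e) for e in parsed], axis=0)
        return _assemble(parsed[0], frames, str(path))
    elements = _read_file(path)
    return _assemble(elements, _frames_from(elements), str(path))


def frame_count_ok(scan: DynamicRenogram, expected: int = 80) -> bool:
    """Frame-count consistency check feeding the exclusion filter."""
    return scan.n_frames == expected
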