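"""Lightweight scan archive: compressed count arrays + a JSON sidecar.

Fast to read and write in tests; the DICOM writer covers interoperability.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .core import AcquisitionMeta, DynamicRenogram, PatientInfo

__all__ = ["save_archive", "load_archive"]


def save_archive(path, scan: DynamicRenogram) -> Path:
    """Write ``<path>.npz`` (counts) and ``<path>.json`` (metadata)."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), counts=scan.counts)
    sidecar = {
        "scan_id": scan.scan_id,
        "patient": dataclasses.asdict(scan.patient),
        "meta": dataclasses.asdict(scan.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def load_archive(path) -> DynamicRenogram:
    path = Path(path)
    counts = np.load(path.with_suffix(".npz"))["counts"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return DynamicRenogram(
        counts=counts,
        meta=AcquisitionMeta(**sidecar["meta"]),
        patient=PatientInfo(**sidecar["patient"]),
        scan_id=sidecar["scan_id"],
    )
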