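"""NIfTI readers/writers, case records, and label remapping.

Internal class indices are contiguous {0,1,2,3}; the BraTS enhancing-tumor
label 4 maps bidirectionally to internal 3 at the I/O boundary.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .volumes import (
    MODALITIES,
    VALID_LABELS,
    InvalidInputError,
    LabelVolume,
    MultimodalVolume,
)


@dataclass
class CaseRecord:
    case_id: str
    modality_paths: dict[str, str]
    label_path: str | None = None
    spacing: tuple[float, float, float] | None = None
    shape: tuple[int, int, int] | None = None
    seed: int | None = None


def record_from_manifest_entry(entry: dict) -> CaseRecord:
    return CaseRecord(
        case_id=entry["case_id"],
        modality_paths=dict(entry["modalities"]),
        label_path=entry.get("label"),
        spacing=tuple(entry["spacing"]) if "spacing" in entry else None,
        seed=entry.get("seed"),
    )


def load_manifest(path: str) -> list[CaseRecord]:
    with open(path) as fh:
        manifest = json.load(fh)
    return [record_from_manifest_entry(e) for e in manifest["cases"]]


def _load_nifti(path: str) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, img.affine, spacing


def read_case(record: CaseRecord) -> tuple[MultimodalVolume, LabelVolume | None]:
    """Load and validate one case: channels stacked (T1, T1C, T2, FLAIR),
    consistent shapes/affines across modalities, labels in {0,1,2,4}."""
    missing = [m for m in MODALITIES if m not in record.modality_paths]
    if missing:
        raise InvalidInputError(f"case {record.case_id!r}: missing modalities {missing}")
    channels, affines, spacings, paths = [], [], [], []
    for m in MODALITIES:
        path = record.modality_paths[m]
        if not os.path.exists(path):
            raise InvalidInputError(f"case {record.case_id!r}: path does not exist: {path}")
        data, affine, spacing = _load_nifti(path)
        channels.append(np.asarray(data, dtype=np.float32))
        affines.append(affine)
        spacings.append(spacing)
        paths.append(path)
    shape0 = channels[0].shape
    for arr, aff, path in zip(channels[1:], affines[1:], paths[1:]):
        if arr.shape != shape0:
            raise InvalidInputError(
                f"modality alignment error: {paths[0]} has shape {shape0} "
                f"but {path} has shape {arr.shape}"
            )
        if not np.allclose(aff, affines[0], atol=1e-4):
            raise InvalidInputError(
                f"modality alignment error: affine of {path} differs from {paths[0]}"
            )
    vol = MultimodalVolume(np.stack(channels), spacing=spacings[0], affine=affines[0])

    labels = None
    if record.label_path is not None:
        lab_data, lab_aff, lab_spacing = _load_nifti(record.label_path)
        lab_arr = np.asarray(lab_data)
        bad = set(np.unique(lab_arr)) - set(VALID_LABELS)
        if bad:
            raise InvalidInputError(
                f"label file {record.label_path}: invalid values {sorted(int(b) for b in bad)}"
            )
        if lab_arr.shape != shape0:
            raise InvalidInputError(
                f"label shape {lab_arr.shape} does not match modalities {shape0}"
            )
        labels = LabelVolume(lab_arr.astype(np.int16), spacing=lab_spacing, affine=lab_aff)
    return vol, labels


def remap_labels(labels: np.ndarray, direction: str) -> np.ndarray:
    """Bijective 4<->3 remap, identity on {0,1,2}.

    ``direction`` is "to_internal" (BraTS {0,1,2,4} -> {0,1,2,3}) or
    "to_brats" (the inverse).  Round trip is the identity.
    """
    lab = np.asarray(labels)
    if direction == "to_internal":
        allowed, src, dst = {0, 1, 2, 4}, 4, 3
    elif direction == "to_brats":
        allowed, src, dst = {0, 1, 2, 3}, 3, 4
    else:
        raise InvalidInputError(f"unknown remap direction {direction!r}")
    bad = set(np.unique(lab)) - allowed
    if bad:
        raise InvalidInputError(f"labels contain values outside coding: {sorted(int(b) for b in bad)}")
    out = lab.copy()
    out[lab == src] = dst
    return out


def save_labels(labels: np.ndarray, affine: np.ndarray, path: str) -> None:
    nib.save(nib.Nifti1Image(np.asarray(labels).astype(np.int16), affine), path)


def save_volume(data: np.ndarray, affine: np.ndarray, path: str) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data).astype(np.float32), affine), path)
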