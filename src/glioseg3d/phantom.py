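"""Synthetic multimodal glioma phantoms.

Generates co-registered 4-channel volumes with nested tumor compartments
(necrotic core, enhancing rim, surrounding edema) inside a spherical brain,
plus additive Gaussian noise and a smooth multiplicative bias field — the
statistical structure needed to exercise every downstream stage without any
external dataset.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .volumes import (
    MODALITIES,
    InvalidSpecError,
    LabelVolume,
    MultimodalVolume,
)

# Tissue keys used by the per-modality contrast table.
TISSUES = ("background", "brain", "net", "et", "ed")

#: Default per-modality mean intensities per tissue, loosely mimicking the
#: relative appearance of glioma compartments on each sequence (e.g. the
#: enhancing rim is bright on T1C, edema bright on T2/FLAIR).
DEFAULT_CONTRASTS: dict[str, dict[str, float]] = {
    "t1": {"background": 0.0, "brain": 0.60, "net": 0.25, "et": 0.45, "ed": 0.50},
    "t1c": {"background": 0.0, "brain": 0.60, "net": 0.20, "et": 0.95, "ed": 0.50},
    "t2": {"background": 0.0, "brain": 0.40, "net": 0.80, "et": 0.55, "ed": 0.85},
    "flair": {"background": 0.0, "brain": 0.45, "net": 0.60, "et": 0.70, "ed": 0.95},
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case; identical spec + seed is bit-reproducible."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_radius_vox: float = 28.0
    tumor_center_vox: tuple[float, float, float] | None = None
    r_net: float = 3.0
    r_et: float = 5.0
    r_ed: float = 8.0
    noise_sigma: float = 0.02
    bias_amplitude: float = 0.1
    modality_contrasts: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_CONTRASTS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n < 16 for n in self.grid_shape):
            raise InvalidSpecError(f"grid_shape must be 3 ints >= 16, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise InvalidSpecError("spacing_mm must be positive")
        if self.brain_radius_vox <= 0:
            raise InvalidSpecError("brain_radius_vox must be positive")
        if self.tumor_center_vox is None:
            self.tumor_center_vox = tuple((n - 1) / 2.0 for n in self.grid_shape)
        if min(self.r_net, self.r_et, self.r_ed) < 0:
            raise InvalidSpecError("tumor radii must be non-negative")
        if not (self.r_net <= self.r_et <= self.r_ed):
            raise InvalidSpecError(
                f"radii must nest r_net <= r_et <= r_ed, got "
                f"({self.r_net}, {self.r_et}, {self.r_ed})"
            )
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be non-negative")
        if self.bias_amplitude < 0:
            raise InvalidSpecError("bias_amplitude must be non-negative")
        # tumor must fit inside the brain sphere
        center = np.asarray(self.tumor_center_vox, dtype=float)
        brain_center = np.asarray([(n - 1) / 2.0 for n in self.grid_shape])
        if np.linalg.norm(center - brain_center) + self.r_ed > self.brain_radius_vox:
            raise InvalidSpecError("tumor (center + r_ed) does not fit inside the brain sphere")
        for m in MODALITIES:
            if m not in self.modality_contrasts:
                raise InvalidSpecError(f"missing contrast table for modality {m!r}")


def _radius_grid(shape: tuple[int, int, int], center: np.ndarray) -> np.ndarray:
    axes = [np.arange(n, dtype=float) for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(
        (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    )


def _polynomial_bias(shape: tuple[int, int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth degree-2 polynomial field rescaled into [1-amplitude, 1+amplitude]."""
    if amplitude == 0:
        return np.ones(shape, dtype=np.float64)
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    basis = [
        np.ones(shape), xx, yy, zz,
        xx * yy, xx * zz, yy * zz,
        xx ** 2, yy ** 2, zz ** 2,
    ]
    coef = rng.standard_normal(len(basis))
    coef[0] = 0.0  # the constant is fixed by the normalisation below
    raw = sum(c * b for c, b in zip(coef, basis))
    centered = raw - raw.mean()  # pins the field's global mean at exactly 1
    peak = np.abs(centered).max()
    if peak < 1e-12:
        return np.ones(shape, dtype=np.float64)
    return 1.0 + amplitude * centered / peak  # within [1-a, 1+a]


def tissue_label_map(spec: PhantomSpec) -> np.ndarray:
    """Integer tissue map: 0 bg, 1 NET, 2 ED, 4 ET; brain marked separately.

    Returns an int array where tumor voxels carry BraTS labels and healthy
    brain is encoded as -1 (internal only, remapped before leaving).
    """
    brain_center = np.asarray([(n - 1) / 2.0 for n in spec.grid_shape])
    r_brain = _radius_grid(spec.grid_shape, brain_center)
    r_tum = _radius_grid(spec.grid_shape, np.asarray(spec.tumor_center_vox, dtype=float))

    lab = np.zeros(spec.grid_shape, dtype=np.int16)
    lab[r_brain <= spec.brain_radius_vox] = -1  # healthy brain
    if spec.r_ed > 0:
        lab[r_tum <= spec.r_ed] = 2  # edema shell (outer)
    if spec.r_et > 0:
        lab[r_tum <= spec.r_et] = 4  # enhancing rim (middle)
    if spec.r_net > 0:
        lab[r_tum <= spec.r_net] = 1  # necrotic core (inner)
    return lab


def generate_phantom(
    spec: PhantomSpec, *, return_clean: bool = False
) -> tuple[MultimodalVolume, LabelVolume] | tuple[MultimodalVolume, LabelVolume, MultimodalVolume]:
    """Generate one synthetic case.

    Each modality channel is tissue-mean map x (1 + bias field) + Gaussian
    noise.  With ``return_clean`` the noiseless, bias-free stack is also
    returned (used as the reference image in enhancement tests).
    """
    rng = np.random.default_rng(spec.seed)
    internal = tissue_label_map(spec)

    tissue_of = {0: "background", -1: "brain", 1: "net", 2: "ed", 4: "et"}
    channels = np.zeros((len(MODALITIES),) + spec.grid_shape, dtype=np.float64)
    for ci, m in enumerate(MODALITIES):
        table = spec.modality_contrasts[m]
        mean_map = np.zeros(spec.grid_shape, dtype=np.float64)
        for code, tissue in tissue_of.items():
            mean_map[internal == code] = table[tissue]
        channels[ci] = mean_map

    clean = channels.copy()
    for ci in range(len(MODALITIES)):
        bias = _polynomial_bias(spec.grid_shape, spec.bias_amplitude, rng)
        noise = rng.normal(0.0, spec.noise_sigma, size=spec.grid_shape)
        channels[ci] = channels[ci] * bias + noise

    labels = internal.copy()
    labels[labels == -1] = 0
    vol = MultimodalVolume(channels.astype(np.float32), spacing=spec.spacing_mm)
    lab = LabelVolume(labels, spacing=spec.spacing_mm)
    if return_clean:
        return vol, lab, MultimodalVolume(clean.astype(np.float32), spacing=spec.spacing_mm)
    return vol, lab


def brain_mask_of(spec: PhantomSpec) -> np.ndarray:
    """Boolean brain mask (sphere) for a phantom spec."""
    brain_center = np.asarray([(n - 1) / 2.0 for n in spec.grid_shape])
    return _radius_grid(spec.grid_shape, brain_center) <= spec.brain_radius_vox


def add_bias_field(vol: MultimodalVolume, amplitude: float, seed: int) -> MultimodalVolume:
    """Multiply each channel by a smooth degree-2 polynomial field in
    [1-amplitude, 1+amplitude] (independent field per channel)."""
    if amplitude < 0:
        raise InvalidSpecError(f"bias amplitude must be >= 0, got {amplitude}")
    rng = np.random.default_rng(seed)
    out = vol.data.astype(np.float64).copy()
    for ci in range(out.shape[0]):
        out[ci] *= _polynomial_bias(vol.grid_shape, amplitude, rng)
    return MultimodalVolume(out.astype(np.float32), spacing=vol.spacing, affine=vol.affine)


def export_dataset(
    cases: list[tuple[MultimodalVolume, LabelVolume]],
    out_dir: str,
    *,
    case_ids: list[str] | None = None,
    seeds: list[int] | None = None,
) -> dict:
    """Write one NIfTI per modality per case plus a label NIfTI and a JSON
    manifest listing paths and seeds.  Returns the manifest dict."""
    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    if case_ids is None:
        case_ids = [f"case{idx:03d}" for idx in range(len(cases))]
    manifest: dict = {"cases": []}
    for idx, ((vol, lab), cid) in enumerate(zip(cases, case_ids)):
        entry: dict = {"case_id": cid, "modalities": {}, "spacing": list(vol.spacing)}
        if seeds is not None:
            entry["seed"] = int(seeds[idx])
        try:
            for ci, m in enumerate(MODALITIES):
                path = os.path.join(out_dir, f"{cid}_{m}.nii.gz")
                nib.save(nib.Nifti1Image(vol.data[ci].astype(np.float32), vol.affine), path)
                entry["modalities"][m] = path
            seg_path = os.path.join(out_dir, f"{cid}_seg.nii.gz")
            nib.save(nib.Nifti1Image(lab.data.astype(np.int16), lab.affine), seg_path)
            entry["label"] = seg_path
        except OSError as exc:  # pragma: no cover - exercised only on I/O failure
            raise OSError(f"failed writing case {cid!r} under {out_dir!r}: {exc}") from exc
        manifest["cases"].append(entry)
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["manifest_path"] = manifest_path
    return manifest


def spec_to_dict(spec: PhantomSpec) -> dict:
    return asdict(spec)
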