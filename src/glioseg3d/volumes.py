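"""Core volume containers and error taxonomy.

All grids use 0-based voxel indices with axis order (x, y, z) matching the
NIfTI affine.  Intensity channels are stacked channel-first in the fixed
modality order (T1, T1C, T2, FLAIR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed channel order for multimodal stacks.
MODALITIES = ("t1", "t1c", "t2", "flair")

#: BraTS label coding: background, necrotic/non-enhancing core, edema,
#: enhancing tumor.
VALID_LABELS = frozenset({0, 1, 2, 4})


class InvalidSpecError(ValueError):
    """A configuration/specification object violates its invariants."""


class InvalidInputError(ValueError):
    """An input array violates an operation's preconditions."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate (e.g. empty mask)."""


class DivergenceError(RuntimeError):
    """Iterative optimisation produced a non-finite objective."""


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class MultimodalVolume:
    """4-channel 3D intensity grid with voxel spacing and affine.

    ``data`` has shape (4, nx, ny, nz), channel order ``MODALITIES``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != len(MODALITIES):
            raise InvalidInputError(
                f"expected (4, nx, ny, nz) intensity stack, got {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise InvalidSpecError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        else:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, modality: str) -> np.ndarray:
        return self.data[MODALITIES.index(modality)]


@dataclass
class LabelVolume:
    """Integer label grid over {0, 1, 2, 4} (BraTS coding)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(self.data == np.round(self.data)):
                raise InvalidInputError("label volume must be integer-valued")
            self.data = self.data.astype(np.int16)
        else:
            self.data = self.data.astype(np.int16)
        if self.data.ndim != 3:
            raise InvalidInputError(f"expected 3D label grid, got {self.data.shape}")
        bad = set(np.unique(self.data)) - set(VALID_LABELS)
        if bad:
            raise InvalidInputError(f"invalid label values {sorted(bad)}; allowed {{0,1,2,4}}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        else:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ProbabilityVolume:
    """Per-voxel class probabilities, shape (num_classes, nx, ny, nz).

    Classes use the *internal* contiguous coding {0,1,2,3}; 3 maps to the
    BraTS enhancing-tumor label 4 at the I/O boundary.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    tol: float = field(default=1e-4, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise InvalidInputError(f"expected (C, nx, ny, nz), got {self.data.shape}")
        sums = self.data.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=self.tol):
            raise InvalidInputError("class probabilities must sum to 1 per voxel")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        else:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def num_classes(self) -> int:
        return self.data.shape[0]

    def argmax_labels(self) -> np.ndarray:
        """Hard labels in internal coding {0..C-1}."""
        return self.data.argmax(axis=0).astype(np.int16)
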