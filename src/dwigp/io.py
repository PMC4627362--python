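"""Standard-format I/O: FSL bvals/bvecs tables and 4D NIfTI volumes.

Gradient directions are interpreted in the image coordinate frame exactly as
given in the bvecs file; no reorientation by the NIfTI affine is attempted.
Sign flips are irrelevant under the axial symmetry of the diffusion signal,
but axis permutations are the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import FormatError, InvalidInputError
from .gradients import (
    DEFAULT_B0_THRESHOLD,
    DEFAULT_SHELL_TOLERANCE,
    GradientScheme,
)


def read_gradient_table(
    bvals_path,
    bvecs_path,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
    shell_tolerance: float = DEFAULT_SHELL_TOLERANCE,
) -> GradientScheme:
    """Parse FSL-style bvals (one row) and bvecs (three rows: x, y, z).

    Vectors are normalised (with a warning when a norm deviates from 1 by
    more than 1e-3); zero vectors are only admissible at b0.
    """
    try:
        bvals = np.loadtxt(bvals_path, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"could not parse bvals file {bvals_path}: {exc}") from exc
    try:
        bvecs = np.loadtxt(bvecs_path, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"could not parse bvecs file {bvecs_path}: {exc}") from exc
    bvals = bvals.ravel()
    if bvecs.shape[0] != 3 and bvecs.shape[1] == 3:
        bvecs = bvecs.T
    if bvecs.shape[0] != 3:
        raise FormatError(
            f"bvecs must have three rows (x, y, z components), got shape {bvecs.shape}"
        )
    if bvecs.shape[1] != len(bvals):
        raise FormatError(
            f"{len(bvals)} b-values but {bvecs.shape[1]} gradient vector columns"
        )
    try:
        return GradientScheme.from_table(bvals, bvecs.T, b0_threshold=b0_threshold,
                                         shell_tolerance=shell_tolerance)
    except InvalidInputError as exc:
        raise FormatError(str(exc)) from exc


def write_gradient_table(scheme: GradientScheme, bvals_path, bvecs_path) -> None:
    """Write a scheme back to FSL bvals/bvecs files."""
    np.savetxt(bvals_path, scheme.bvalues[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, scheme.directions.T, fmt="%.9f")


@dataclass
class DatasetBundle:
    """A 4D acquisition with its gradient scheme and optional brain mask."""

    volumes: np.ndarray
    scheme: GradientScheme
    mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volumes.ndim != 4:
            raise FormatError(f"expected a 4D volume array, got {self.volumes.ndim}D")
        if self.volumes.shape[3] != len(self.scheme):
            raise FormatError(
                f"data has {self.volumes.shape[3]} volumes but the gradient "
                f"table describes {len(self.scheme)}"
            )
        if self.mask is not None and self.mask.shape != self.volumes.shape[:3]:
            raise FormatError(
                f"mask shape {self.mask.shape} does not match spatial "
                f"dimensions {self.volumes.shape[:3]}"
            )

    def voxel_matrix(self) -> np.ndarray:
        """Masked voxels as a (V, n_volumes) matrix."""
        if self.mask is None:
            return self.volumes.reshape(-1, self.volumes.shape[3])
        return self.volumes[self.mask.astype(bool)]

    def unflatten(self, per_voxel: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-voxel vector back into a 3D volume."""
        out = np.full(self.volumes.shape[:3], fill, dtype=float)
        if self.mask is None:
            out[...] = per_voxel.reshape(self.volumes.shape[:3])
        else:
            out[self.mask.astype(bool)] = per_voxel
        return out


def read_volumes(path, mask_path=None) -> tuple[np.ndarray, np.ndarray | None, nib.Nifti1Image]:
    """Load a 4D NIfTI (and optional 3D mask); returns (data, mask, image)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D volume, got {data.ndim}D")
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise FormatError(
                f"mask shape {mask.shape} does not match data {data.shape[:3]}"
            )
    return data, mask, img


def write_volumes(array: np.ndarray, reference: nib.Nifti1Image | np.ndarray, path) -> None:
    """Write an array as NIfTI reusing the reference's affine (or an affine)."""
    affine = reference.affine if hasattr(reference, "affine") else np.asarray(reference)
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine), str(path))


def load_dataset(data_path, bvals_path, bvecs_path, mask_path=None,
                 b0_threshold: float = DEFAULT_B0_THRESHOLD,
                 shell_tolerance: float = DEFAULT_SHELL_TOLERANCE) -> DatasetBundle:
    """Assemble a :class:`DatasetBundle` from files on disk."""
    scheme = read_gradient_table(bvals_path, bvecs_path,
                                 b0_threshold=b0_threshold,
                                 shell_tolerance=shell_tolerance)
    data, mask, img = read_volumes(data_path, mask_path)
    bundle = DatasetBundle(volumes=data, scheme=scheme, mask=mask,
                           provenance={"data": str(data_path),
                                       "bvals": str(bvals_path),
                                       "bvecs": str(bvecs_path),
                                       "mask": str(mask_path) if mask_path else None})
    bundle.provenance["image"] = img
    return bundle
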