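"""Gradient schemes: diffusion directions, b-values and shell structure.

A diffusion acquisition is described by one unit gradient direction and one
b-value (s/mm^2) per volume.  Volumes with b below a threshold are treated as
non-diffusion-weighted (b0) reference volumes and are excluded from Gaussian
process training and prediction.  The remaining b-values are clustered into
shells around representative b-values, since scanners jitter the nominal
weighting slightly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .exceptions import InvalidInputError

#: b-values at or below this count as b0 (s/mm^2).
DEFAULT_B0_THRESHOLD = 50.0
#: absolute tolerance for assigning a b-value to a shell (s/mm^2).
DEFAULT_SHELL_TOLERANCE = 100.0

_UNIT_NORM_TOL = 1e-6


def _cluster_shells(bvalues: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Greedy 1-D clustering of non-b0 b-values into shells.

    Returns (shell_ids, shell_bvalues) with shell_bvalues strictly increasing
    and each representative the mean of its members.
    """
    order = np.argsort(bvalues)
    reps: list[float] = []
    members: list[list[int]] = []
    for idx in order:
        b = bvalues[idx]
        if reps and abs(b - reps[-1]) <= tol:
            members[-1].append(idx)
            reps[-1] = float(np.mean(bvalues[members[-1]]))
        else:
            reps.append(float(b))
            members.append([idx])
    shell_ids = np.empty(len(bvalues), dtype=np.intp)
    for s, idxs in enumerate(members):
        shell_ids[idxs] = s
    shell_bvalues = np.asarray(reps, dtype=float)
    if np.any(np.diff(shell_bvalues) <= 0):
        raise InvalidInputError(
            "shell clustering produced non-increasing representative b-values; "
            "decrease the shell tolerance"
        )
    return shell_ids, shell_bvalues


@dataclass(frozen=True, eq=False)
class GradientScheme:
    """Directions, b-values and shell assignment for a whole acquisition.

    Parameters
    ----------
    directions : (n, 3) float array
        Unit diffusion-gradient directions.  Rows belonging to b0 volumes may
        be zero vectors.
    bvalues : (n,) float array
        Non-negative diffusion weightings in s/mm^2.
    shell_ids : (n,) int array
        Shell index in [0, n_shells) for diffusion-weighted volumes, -1 for b0.
    shell_bvalues : (n_shells,) float array
        Strictly increasing representative b-value per shell.
    """

    directions: np.ndarray
    bvalues: np.ndarray
    shell_ids: np.ndarray
    shell_bvalues: np.ndarray

    def __post_init__(self) -> None:
        directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        shell_ids = np.asarray(self.shell_ids, dtype=np.intp).ravel()
        shell_bvalues = np.asarray(self.shell_bvalues, dtype=float).ravel()
        if directions.shape != (len(bvalues), 3):
            raise InvalidInputError(
                f"directions shape {directions.shape} does not match "
                f"{len(bvalues)} b-values"
            )
        if len(shell_ids) != len(bvalues):
            raise InvalidInputError("shell_ids and bvalues differ in length")
        if np.any(bvalues < 0):
            raise InvalidInputError("b-values must be non-negative")
        dwi = shell_ids >= 0
        if np.any(shell_ids[dwi] >= len(shell_bvalues)):
            raise InvalidInputError("shell_id outside [0, n_shells)")
        if len(shell_bvalues) and np.any(np.diff(shell_bvalues) <= 0):
            raise InvalidInputError("shell_bvalues must be strictly increasing")
        norms = np.linalg.norm(directions[dwi], axis=1)
        bad = np.flatnonzero(np.abs(norms - 1.0) > _UNIT_NORM_TOL)
        if bad.size:
            i = int(np.flatnonzero(dwi)[bad[0]])
            raise InvalidInputError(
                f"direction {i} has norm {np.linalg.norm(directions[i]):.6g}, "
                "expected unit length"
            )
        for arr, name in ((directions, "directions"), (bvalues, "bvalues"),
                          (shell_ids, "shell_ids"), (shell_bvalues, "shell_bvalues")):
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_table(
        cls,
        bvals: np.ndarray,
        bvecs: np.ndarray,
        b0_threshold: float = DEFAULT_B0_THRESHOLD,
        shell_tolerance: float = DEFAULT_SHELL_TOLERANCE,
    ) -> "GradientScheme":
        """Build a scheme from raw b-values and (possibly unnormalised) vectors.

        ``bvecs`` is (n, 3) or (3, n).  Non-b0 vectors are normalised to unit
        length; a warning is emitted if a norm deviates from 1 by more than
        1e-3 before normalisation.
        """
        bvals = np.asarray(bvals, dtype=float).ravel()
        bvecs = np.asarray(bvecs, dtype=float)
        if bvecs.shape == (3, len(bvals)) and bvecs.shape[0] != bvecs.shape[1]:
            bvecs = bvecs.T
        if bvecs.shape != (len(bvals), 3):
            raise InvalidInputError(
                f"{len(bvals)} b-values but gradient vectors of shape {bvecs.shape}"
            )
        bvecs = bvecs.copy()
        is_b0 = bvals <= b0_threshold
        norms = np.linalg.norm(bvecs, axis=1)
        zero_dwi = np.flatnonzero((norms == 0) & ~is_b0)
        if zero_dwi.size:
            raise InvalidInputError(
                f"zero gradient vector at index {int(zero_dwi[0])} with "
                f"b={bvals[zero_dwi[0]]:.1f} > b0 threshold {b0_threshold:.1f}"
            )
        off = np.flatnonzero(~is_b0 & (np.abs(norms - 1.0) > 1e-3))
        if off.size:
            warnings.warn(
                f"{off.size} gradient vector(s) deviate from unit norm by more "
                "than 1e-3 (max |norm-1| = "
                f"{np.max(np.abs(norms[off] - 1.0)):.3g}); normalising",
                stacklevel=2,
            )
        bvecs[~is_b0] /= norms[~is_b0, None]
        bvecs[is_b0] = 0.0

        shell_ids = np.full(len(bvals), -1, dtype=np.intp)
        dwi_idx = np.flatnonzero(~is_b0)
        if dwi_idx.size:
            ids, shell_bvalues = _cluster_shells(bvals[dwi_idx], shell_tolerance)
            shell_ids[dwi_idx] = ids
        else:
            shell_bvalues = np.empty(0)
        return cls(bvecs, bvals, shell_ids, shell_bvalues)

    # -- basic views -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def n_shells(self) -> int:
        return len(self.shell_bvalues)

    @property
    def is_b0(self) -> np.ndarray:
        return self.shell_ids < 0

    @property
    def dwi_indices(self) -> np.ndarray:
        """Indices of diffusion-weighted (non-b0) volumes."""
        return np.flatnonzero(~self.is_b0)

    @cached_property
    def dwi(self) -> "GradientScheme":
        """The scheme restricted to diffusion-weighted volumes."""
        if not np.any(self.is_b0):
            return self
        idx = self.dwi_indices
        return GradientScheme(
            self.directions[idx], self.bvalues[idx],
            self.shell_ids[idx], self.shell_bvalues,
        )

    def subset(self, indices: np.ndarray) -> "GradientScheme":
        """A sub-scheme at ``indices`` retaining the full shell labelling."""
        indices = np.asarray(indices, dtype=np.intp)
        return GradientScheme(
            self.directions[indices], self.bvalues[indices],
            self.shell_ids[indices], self.shell_bvalues,
        )

    def shell_members(self, shell: int) -> np.ndarray:
        """Indices (within this scheme) belonging to ``shell``."""
        if not 0 <= shell < self.n_shells:
            raise InvalidInputError(f"no shell {shell} in a {self.n_shells}-shell scheme")
        return np.flatnonzero(self.shell_ids == shell)
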