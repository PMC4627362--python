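"""Synthetic gradient schemes and diffusion-weighted signals.

The simulator provides everything the GP machinery needs for end-to-end
validation without scanner data: acquisition schemes with one or more
b-shells (random directions or electrostatic-repulsion spacing), noise-free
multi-tensor voxel signals, Gaussian/Rician noise, and a small tissue
phantom with white-matter (single and crossing fibre), grey-matter and CSF
voxel classes.

The multi-tensor signal model is

    S(g, b) = S0 [ sum_i f_i exp(-b g^T D_i g) + f_iso exp(-b d_iso) ]

with D_i the axially symmetric diffusion tensor of fibre population i and
the isotropic compartment taking up the remaining volume fraction.  The
noise-free signal is exactly antipodally symmetric and decays monotonically
with b, matching the assumptions of the GP covariance models.

Default diffusivities are textbook human-brain magnitudes: axial 1.7e-3,
radial 0.2e-3, CSF 3.0e-3 and grey matter 0.8e-3 mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError
from .gradients import GradientScheme

AXIAL_DIFFUSIVITY = 1.7e-3
RADIAL_DIFFUSIVITY = 0.2e-3
CSF_DIFFUSIVITY = 3.0e-3
GM_DIFFUSIVITY = 0.8e-3

PHANTOM_CLASSES = ("wm1", "wm2_crossing", "wm3_crossing", "gm", "csf")


@dataclass(frozen=True)
class FiberPopulation:
    """One axially symmetric fibre compartment of a voxel."""

    orientation: np.ndarray
    volume_fraction: float
    axial_diffusivity: float = AXIAL_DIFFUSIVITY
    radial_diffusivity: float = RADIAL_DIFFUSIVITY

    def __post_init__(self) -> None:
        v = np.asarray(self.orientation, dtype=float).ravel()
        n = np.linalg.norm(v)
        if n == 0:
            raise InvalidInputError("fibre orientation must be a non-zero vector")
        object.__setattr__(self, "orientation", v / n)
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise InvalidInputError("volume fraction must lie in [0, 1]")
        if not self.axial_diffusivity >= self.radial_diffusivity >= 0.0:
            raise InvalidInputError("need axial >= radial >= 0 diffusivity")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise description: kind, standard deviation and seed."""

    kind: str = "rician"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "rician", "none"):
            raise InvalidInputError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise InvalidInputError("noise sigma must be non-negative")


# ---------------------------------------------------------------------------
# gradient schemes
# ---------------------------------------------------------------------------

def _random_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _repulsion_directions(n: int, rng: np.random.Generator,
                          n_iter: int = 300) -> np.ndarray:
    """Electrostatic repulsion on antipodally symmetrised points.

    Coulomb forces from every other point and its antipode are projected on
    the tangent plane, with a decaying step; this spreads the minimum
    pairwise axial angle well beyond random placement.
    """
    x = _random_directions(n, rng)
    for it in range(n_iter):
        step = 0.05 * (1.0 - it / n_iter) / np.sqrt(n)
        diff_m = x[:, None, :] - x[None, :, :]
        diff_p = x[:, None, :] + x[None, :, :]
        dm = np.linalg.norm(diff_m, axis=2)
        dp = np.linalg.norm(diff_p, axis=2)
        np.fill_diagonal(dm, np.inf)
        np.fill_diagonal(dp, np.inf)
        force = (diff_m / dm[..., None] ** 3).sum(axis=1) \
            + (diff_p / dp[..., None] ** 3).sum(axis=1)
        force -= np.sum(force * x, axis=1, keepdims=True) * x  # tangential part
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        x = x + step * force / norm
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def make_scheme(
    n_per_shell,
    shell_bvalues,
    n_b0: int = 0,
    seed: int = 0,
    method: str = "random",
) -> GradientScheme:
    """Generate an acquisition scheme with the requested shells.

    ``method`` is "random" (uniform on the sphere) or "repulsion"
    (electrostatic spacing, better minimum axial angle).  b0 volumes, if
    any, are placed first with zero gradient vectors.  Deterministic given
    ``seed``.
    """
    n_per_shell = [int(c) for c in np.atleast_1d(n_per_shell)]
    shell_bvalues = np.asarray(shell_bvalues, dtype=float).ravel()
    if len(n_per_shell) == 0 or len(shell_bvalues) == 0:
        raise InvalidInputError("at least one shell is required")
    if len(n_per_shell) != len(shell_bvalues):
        raise InvalidInputError("n_per_shell and shell_bvalues differ in length")
    if any(c < 1 for c in n_per_shell):
        raise InvalidInputError("every shell needs at least one direction")
    if np.any(shell_bvalues <= 0) or len(np.unique(shell_bvalues)) != len(shell_bvalues):
        raise InvalidInputError("shell b-values must be positive and distinct")
    if method not in ("random", "repulsion"):
        raise InvalidInputError(f"unknown placement method {method!r}")
    order = np.argsort(shell_bvalues)
    rng = np.random.default_rng(seed)
    directions = [np.zeros((int(n_b0), 3))]
    bvals = [np.zeros(int(n_b0))]
    ids = [np.full(int(n_b0), -1, dtype=np.intp)]
    for rank, s in enumerate(order):
        n = n_per_shell[s]
        pts = _random_directions(n, rng)
        if method == "repulsion":
            pts = _repulsion_directions(n, rng)
        directions.append(pts)
        bvals.append(np.full(n, shell_bvalues[s]))
        ids.append(np.full(n, rank, dtype=np.intp))
    return GradientScheme(
        np.concatenate(directions), np.concatenate(bvals),
        np.concatenate(ids), shell_bvalues[order],
    )


def min_axial_angle(directions: np.ndarray) -> float:
    """Smallest pairwise axial angle (radians) of a direction set."""
    from .kernels import compute_angles

    theta = compute_angles(directions)
    return float(np.min(theta[np.triu_indices_from(theta, k=1)]))


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def simulate_voxel(
    fibers,
    iso_diffusivity: float = GM_DIFFUSIVITY,
    s0: float = 100.0,
    scheme: GradientScheme | None = None,
) -> np.ndarray:
    """Noise-free multi-tensor signal for every volume of ``scheme``.

    Returns a full-length signal vector aligned with the scheme, b0 entries
    included (they equal ``s0`` exactly).  The isotropic compartment's
    fraction is 1 minus the summed fibre fractions.
    """
    if scheme is None:
        raise InvalidInputError("a gradient scheme is required")
    if not s0 > 0:
        raise InvalidInputError("s0 must be positive")
    fibers = list(fibers)
    f_total = sum(f.volume_fraction for f in fibers)
    if f_total > 1.0 + 1e-12:
        raise InvalidInputError(f"fibre fractions sum to {f_total:.3f} > 1")
    f_iso = max(0.0, 1.0 - f_total)
    g = scheme.directions
    b = scheme.bvalues
    signal = f_iso * np.exp(-b * float(iso_diffusivity))
    for f in fibers:
        proj = g @ f.orientation
        # g^T D g for an axially symmetric tensor
        adc = f.radial_diffusivity + \
            (f.axial_diffusivity - f.radial_diffusivity) * proj**2
        signal = signal + f.volume_fraction * np.exp(-b * adc)
    signal = s0 * signal
    signal[scheme.is_b0] = s0  # zero gradient vectors carry no weighting
    return signal


def add_noise(signal: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Apply the observation-noise model; identity for kind="none" or sigma=0."""
    signal = np.asarray(signal, dtype=float)
    if noise.kind == "none" or noise.sigma == 0.0:
        return signal.copy()
    rng = np.random.default_rng(noise.seed)
    if noise.kind == "gaussian":
        return signal + rng.normal(0.0, noise.sigma, size=signal.shape)
    e1 = rng.normal(0.0, noise.sigma, size=signal.shape)
    e2 = rng.normal(0.0, noise.sigma, size=signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)


# ---------------------------------------------------------------------------
# tissue phantom
# ---------------------------------------------------------------------------

def _jitter_rotation(rng: np.random.Generator, sigma: float = 0.05) -> np.ndarray:
    """Small random rotation: axis uniform on the sphere, angle ~ |N(0, sigma)|."""
    axis = _random_directions(1, rng)[0]
    angle = rng.normal(0.0, sigma)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _class_fibers(label: str, rotation: np.ndarray) -> tuple[list, float]:
    """Canonical fibre configuration and isotropic diffusivity for a class."""
    x, y, z = np.eye(3)
    if label == "wm1":
        fibers = [FiberPopulation(rotation @ x, 0.85)]
        iso = GM_DIFFUSIVITY
    elif label == "wm2_crossing":
        fibers = [FiberPopulation(rotation @ x, 0.425),
                  FiberPopulation(rotation @ y, 0.425)]
        iso = GM_DIFFUSIVITY
    elif label == "wm3_crossing":
        fibers = [FiberPopulation(rotation @ x, 0.3),
                  FiberPopulation(rotation @ y, 0.3),
                  FiberPopulation(rotation @ z, 0.3)]
        iso = GM_DIFFUSIVITY
    elif label == "gm":
        fibers = []
        iso = GM_DIFFUSIVITY
    elif label == "csf":
        fibers = []
        iso = CSF_DIFFUSIVITY
    else:
        raise InvalidInputError(
            f"unknown phantom class {label!r}; expected one of {PHANTOM_CLASSES}"
        )
    return fibers, iso


@dataclass(frozen=True)
class Phantom:
    """Simulated voxel population: (V, n) signals with per-voxel class labels."""

    signals: np.ndarray
    labels: np.ndarray
    scheme: GradientScheme
    noise_free: np.ndarray

    def to_4d(self) -> tuple[np.ndarray, np.ndarray]:
        """Reshape to a (V, 1, 1, n) volume plus (V, 1, 1) label array."""
        V, n = self.signals.shape
        return self.signals.reshape(V, 1, 1, n), self.labels.reshape(V, 1, 1)


def make_phantom(
    n_voxels_per_class,
    scheme: GradientScheme,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    s0: float = 100.0,
    orientation_jitter: float = 0.05,
) -> Phantom:
    """Simulate a labelled voxel population over the given scheme.

    ``n_voxels_per_class`` maps class names (wm1, wm2_crossing, wm3_crossing,
    gm, csf) to voxel counts.  Fibre orientations are jittered per voxel by a
    small random rotation; noise is applied after the noise-free signal.
    Fully reproducible from ``seed``.
    """
    if not n_voxels_per_class:
        raise InvalidInputError("at least one voxel class is required")
    noise = noise or NoiseSpec(kind="none")
    rng = np.random.default_rng(seed)
    clean, labels = [], []
    for label, count in n_voxels_per_class.items():
        if label not in PHANTOM_CLASSES:
            raise InvalidInputError(
                f"unknown phantom class {label!r}; expected one of {PHANTOM_CLASSES}"
            )
        for _ in range(int(count)):
            R = _jitter_rotation(rng, orientation_jitter)
            fibers, iso = _class_fibers(label, R)
            clean.append(simulate_voxel(fibers, iso, s0, scheme))
            labels.append(label)
    clean = np.asarray(clean)
    noisy = add_noise(clean, NoiseSpec(noise.kind, noise.sigma,
                                       seed=int(rng.integers(2**31))))
    return Phantom(signals=noisy, labels=np.asarray(labels),
                   scheme=scheme, noise_free=clean)
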