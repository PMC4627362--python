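"""Gaussian-process conditioning for diffusion-weighted signals.

Given a kernel K_y = K + noise assembled from a gradient scheme, the signal
in one voxel is predicted at arbitrary (direction, b-value) points via the
usual multivariate-normal conditioning:

    mean(x*) = k(x*, x)^T K_y^{-1} (f - fbar) + fbar
    var(x*)  = k(x*, x*) - k(x*, x)^T K_y^{-1} k(x, x*)

The process is zero-mean, so the per-shell mean signal fbar_s is subtracted
before conditioning and restored at the query.  Shells attenuate very
differently, so pooling the mean across shells would bias cross-shell
predictions; queries at b-values not acquired get a mean interpolated
linearly in log b and are flagged as extrapolated.

The predictive variance depends only on geometry and hyperparameters, never
on the observed values; prediction for a whole population of voxels reuses a
single factorisation and is therefore linear and fast per voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, NumericalConditioningError
from .gradients import DEFAULT_SHELL_TOLERANCE, GradientScheme
from .kernels import Hyperparameters, KernelMatrix, assemble_K, cross_covariance

_LOG_2PI = float(np.log(2.0 * np.pi))
#: predictive variances in (-1e-9 * lam, 0) are clamped to 0; worse is an error
_VARIANCE_SLACK = 1e-9


@dataclass(frozen=True, eq=False)
class VoxelSignal:
    """One voxel's diffusion-weighted measurements aligned to a scheme.

    ``values`` holds only the non-b0 measurements; ``scheme`` is the matching
    b0-free :class:`GradientScheme`.
    """

    values: np.ndarray
    scheme: GradientScheme

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        if np.any(self.scheme.is_b0):
            raise InvalidInputError("VoxelSignal scheme must be b0-free (use scheme.dwi)")
        if len(values) != len(self.scheme):
            raise InvalidInputError(
                f"{len(values)} values but scheme has {len(self.scheme)} measurements"
            )
        object.__setattr__(self, "values", values)

    @classmethod
    def from_full(cls, values: np.ndarray, scheme: GradientScheme) -> "VoxelSignal":
        """Build from a full-acquisition signal vector, dropping b0 entries."""
        values = np.asarray(values, dtype=float).ravel()
        if len(values) != len(scheme):
            raise InvalidInputError(
                f"{len(values)} values but acquisition has {len(scheme)} volumes"
            )
        return cls(values[scheme.dwi_indices], scheme.dwi)

    @cached_property
    def shell_means(self) -> np.ndarray:
        """Mean signal fbar_s per shell."""
        return shell_means(self.values[None, :], self.scheme)[0]

    @cached_property
    def demeaned(self) -> np.ndarray:
        return self.values - self.shell_means[self.scheme.shell_ids]


@dataclass(frozen=True)
class Prediction:
    """Predictive mean and variance at query (direction, b-value) points."""

    mean: np.ndarray
    variance: np.ndarray
    mode: str
    extrapolated: np.ndarray  # True where the query b-value matched no shell


def shell_means(values: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    """Per-shell mean signal, vectorised over voxels: (V, n) -> (V, S)."""
    values = np.atleast_2d(values)
    out = np.full((values.shape[0], scheme.n_shells), np.nan)
    for s in range(scheme.n_shells):
        members = scheme.shell_ids == s
        if members.any():  # a subset scheme may have empty shells
            out[:, s] = values[:, members].mean(axis=1)
    return out


def _demean(values: np.ndarray, scheme: GradientScheme) -> tuple[np.ndarray, np.ndarray]:
    means = shell_means(values, scheme)
    return np.atleast_2d(values) - means[:, scheme.shell_ids], means


def _match_shells(
    scheme: GradientScheme, query_bvalues: np.ndarray, tol: float
) -> np.ndarray:
    """Nearest shell per query b-value, or -1 where none is within ``tol``."""
    qb = np.asarray(query_bvalues, dtype=float).ravel()
    if np.any(qb <= 0):
        i = int(np.flatnonzero(qb <= 0)[0])
        raise InvalidInputError(f"query b-value {qb[i]} at index {i} must be positive")
    d = np.abs(qb[:, None] - scheme.shell_bvalues[None, :])
    nearest = np.argmin(d, axis=1)
    nearest[d[np.arange(len(qb)), nearest] > tol] = -1
    return nearest


def _query_means(
    means: np.ndarray,
    scheme: GradientScheme,
    query_shells: np.ndarray,
    query_bvalues: np.ndarray,
) -> np.ndarray:
    """Restore the mean at each query: shell mean, or log-b interpolation."""
    qb = np.asarray(query_bvalues, dtype=float).ravel()
    out = np.empty((means.shape[0], len(query_shells)))
    matched = query_shells >= 0
    out[:, matched] = means[:, query_shells[matched]]
    if np.any(~matched):
        logb = np.log(scheme.shell_bvalues)
        for v in range(means.shape[0]):
            out[v, ~matched] = np.interp(np.log(qb[~matched]), logb, means[v])
    return out


def _prepare_queries(scheme, query_directions, query_bvalues, shell_tolerance):
    Q = np.atleast_2d(np.asarray(query_directions, dtype=float))
    if query_bvalues is None:
        if scheme.n_shells != 1:
            raise InvalidInputError("multi-shell prediction requires query b-values")
        qb = np.full(Q.shape[0], scheme.shell_bvalues[0])
    else:
        qb = np.asarray(query_bvalues, dtype=float).ravel()
        if len(qb) == 1 and Q.shape[0] > 1:
            qb = np.full(Q.shape[0], qb[0])
    if Q.shape[0] != len(qb):
        raise InvalidInputError(
            f"{Q.shape[0]} query directions but {len(qb)} query b-values"
        )
    qshell = _match_shells(scheme, qb, shell_tolerance)
    if scheme.n_shells == 1 and np.any(qshell < 0):
        i = int(np.flatnonzero(qshell < 0)[0])
        raise InvalidInputError(
            f"query b-value {qb[i]:.1f} does not match the single acquired "
            f"shell b={scheme.shell_bvalues[0]:.1f}"
        )
    # snap matched queries to the representative shell b-value so the log-b
    # factor is exactly 1 within shell, as in training
    kb = np.where(qshell >= 0, scheme.shell_bvalues[np.maximum(qshell, 0)], qb)
    return Q, qb, kb, qshell


def predict(
    voxel: VoxelSignal | np.ndarray,
    hyper: Hyperparameters,
    query_directions: np.ndarray,
    query_bvalues: np.ndarray | None = None,
    *,
    scheme: GradientScheme | None = None,
    kernel: KernelMatrix | None = None,
    shell_tolerance: float = DEFAULT_SHELL_TOLERANCE,
    mode: str = "smoothing",
) -> Prediction:
    """Predictive mean and variance for one voxel (or a stack of voxels).

    ``voxel`` is a :class:`VoxelSignal`, or a (V, n) array of many voxels'
    values with ``scheme`` given explicitly (the mean is then a (V, m) array).
    A pre-assembled ``kernel`` for (scheme, hyper) is reused when supplied.
    """
    if isinstance(voxel, VoxelSignal):
        sch = voxel.scheme
        values = voxel.values[None, :]
        squeeze = True
    else:
        if scheme is None:
            raise InvalidInputError("raw voxel arrays require an explicit scheme")
        sch = scheme.dwi
        values = np.atleast_2d(np.asarray(voxel, dtype=float))
        squeeze = values.ndim == 1 or np.asarray(voxel).ndim == 1
    if values.shape[1] != len(sch):
        raise InvalidInputError(
            f"voxel has {values.shape[1]} values but scheme has {len(sch)}"
        )
    if kernel is None:
        kernel = assemble_K(sch, hyper)
    Q, qb, kb, qshell = _prepare_queries(sch, query_directions, query_bvalues,
                                         shell_tolerance)
    k_star = cross_covariance(sch, hyper, Q, kb if sch.n_shells > 1 else None)
    demeaned, means = _demean(values, sch)
    mean = k_star @ kernel.solve(demeaned.T) + _query_means(means, sch, qshell, qb).T
    var = _predictive_variance(kernel, k_star, hyper.lam)
    extrapolated = qshell < 0
    if squeeze:
        mean = mean[:, 0]
    return Prediction(mean=mean.T if not squeeze else mean, variance=var,
                      mode=mode, extrapolated=extrapolated)


def _predictive_variance(kernel: KernelMatrix, k_star: np.ndarray, lam: float) -> np.ndarray:
    v = kernel.solve(k_star.T)
    var = lam - np.sum(k_star * v.T, axis=1)
    worst = float(var.min(initial=0.0))
    if worst < -_VARIANCE_SLACK * lam:
        raise NumericalConditioningError(
            f"predictive variance {worst:.3g} is negative beyond the "
            f"floating-point slack {-_VARIANCE_SLACK * lam:.3g}"
        )
    if worst < 0:
        warnings.warn("clamping a slightly negative predictive variance to 0",
                      stacklevel=2)
        var = np.maximum(var, 0.0)
    return var


def predict_mean(voxel, hyper, query_directions, query_bvalues=None, **kw) -> np.ndarray:
    """Predictive mean only (see :func:`predict`)."""
    return predict(voxel, hyper, query_directions, query_bvalues, **kw).mean


def predict_variance(voxel, hyper, query_directions, query_bvalues=None, **kw) -> np.ndarray:
    """Predictive variance only; independent of the observed values."""
    return predict(voxel, hyper, query_directions, query_bvalues, **kw).variance


# ---------------------------------------------------------------------------
# marginal likelihood and leave-one-out criteria
# ---------------------------------------------------------------------------

def log_marginal_likelihood(voxel: VoxelSignal | np.ndarray, kernel: KernelMatrix) -> float:
    """Type-II log marginal likelihood of one voxel under the kernel.

    -1/2 y^T K_y^{-1} y - 1/2 log|K_y| - (n/2) log 2pi with y the (per-shell)
    demeaned signal.  A plain array is taken as an already demeaned y.
    """
    y = voxel.demeaned if isinstance(voxel, VoxelSignal) else np.asarray(voxel, float).ravel()
    if len(y) != kernel.n:
        raise InvalidInputError(f"{len(y)} values but kernel is {kernel.n} x {kernel.n}")
    quad = float(y @ kernel.solve(y))
    return -0.5 * quad - 0.5 * kernel.log_det - 0.5 * kernel.n * _LOG_2PI


def loo_criteria(voxel: VoxelSignal | np.ndarray, kernel: KernelMatrix) -> tuple[float, float]:
    """Leave-one-out scores from the factorised full system.

    Uses the closed-form GP LOO identities: with A = K_y^{-1} and
    alpha = A y, point i's LOO residual is alpha_i / A_ii and its predictive
    variance 1 / A_ii.  Returns (cv, gpp): the mean squared LOO residual
    (minimise) and the mean LOO log predictive density (maximise).
    """
    y = voxel.demeaned if isinstance(voxel, VoxelSignal) else np.asarray(voxel, float).ravel()
    if len(y) != kernel.n:
        raise InvalidInputError(f"{len(y)} values but kernel is {kernel.n} x {kernel.n}")
    A = kernel.inverse()
    d = np.diag(A).copy()
    if np.any(d <= 0):
        raise NumericalConditioningError(
            "non-positive leave-one-out predictive variance (ill-conditioned K_y)"
        )
    resid = (A @ y) / d
    var = 1.0 / d
    cv = float(np.mean(resid**2))
    gpp = float(np.mean(-0.5 * np.log(2.0 * np.pi * var) - resid**2 / (2.0 * var)))
    return cv, gpp


# ---------------------------------------------------------------------------
# prior sampling
# ---------------------------------------------------------------------------

def sample_prior(
    scheme: GradientScheme,
    hyper: Hyperparameters,
    n_draws: int,
    seed: int,
    mean: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Draw signal shapes from the GP prior N(mean, K) on a scheme.

    Returns an (n_draws, n) array; the same seed reproduces the same draws.
    A relative jitter of 1e-10 * lam stabilises the Cholesky factor of the
    noise-free K.
    """
    if n_draws < 1:
        raise InvalidInputError("n_draws must be at least 1")
    sch = scheme.dwi
    kernel = assemble_K(sch, hyper)
    K = kernel.K + 1e-10 * hyper.lam * np.eye(kernel.n)
    L = np.linalg.cholesky(K)
    rng = np.random.default_rng(seed)
    return rng.standard_normal((int(n_draws), kernel.n)) @ L.T + mean


# ---------------------------------------------------------------------------
# whole-volume prediction and shell subsampling
# ---------------------------------------------------------------------------

def predict_volume(
    signals: np.ndarray,
    scheme: GradientScheme,
    hyper: Hyperparameters,
    target_index: int,
    include_self: bool = False,
) -> np.ndarray:
    """Predict one acquired volume for every voxel.

    ``signals`` is (V, n_total) aligned with the *full* scheme (b0 included);
    ``target_index`` names a non-b0 volume.  With ``include_self`` the
    observed volume stays in the training set (smoothing on the sphere);
    without it the volume is excluded and the GP interpolates.  Returns the
    (V,) predicted signal at the target's (direction, b-value).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[1] != len(scheme):
        raise InvalidInputError(
            f"signals have {signals.shape[1]} volumes but scheme has {len(scheme)}"
        )
    target_index = int(target_index)
    if not 0 <= target_index < len(scheme):
        raise InvalidInputError(f"target_index {target_index} out of range")
    if scheme.is_b0[target_index]:
        raise InvalidInputError(
            f"volume {target_index} is a b0 volume; GP prediction applies to "
            "diffusion-weighted volumes only"
        )
    dwi_idx = scheme.dwi_indices
    pos = int(np.flatnonzero(dwi_idx == target_index)[0])
    dwi_scheme = scheme.dwi
    train_pos = np.arange(len(dwi_scheme)) if include_self else \
        np.delete(np.arange(len(dwi_scheme)), pos)
    train_scheme = dwi_scheme.subset(train_pos)
    train_values = signals[:, dwi_idx[train_pos]]
    g = dwi_scheme.directions[pos][None, :]
    b = np.array([dwi_scheme.shell_bvalues[dwi_scheme.shell_ids[pos]]])
    pred = predict(train_values, hyper, g, b, scheme=train_scheme,
                   mode="smoothing" if include_self else "interpolation")
    return np.asarray(pred.mean).reshape(signals.shape[0])


def shell_subsample_experiment(
    voxel: VoxelSignal,
    hyper: Hyperparameters,
    target_shell: int,
    n_points_list,
    support_shells,
    truth: np.ndarray | None = None,
    order: np.ndarray | None = None,
) -> pd.DataFrame:
    """RMSE of reconstructing one shell from subsets, with and without support.

    For each subset size the full target shell is predicted (a) from the
    subset alone and (b) from the subset plus each supporting shell in turn;
    the table reports the RMSE against ``truth`` (default: the voxel's own
    values on the target shell).  ``order`` permutes the target-shell points
    before taking the leading subset; the default is acquisition order.
    """
    sch = voxel.scheme
    tgt = sch.shell_members(target_shell)
    if truth is None:
        truth = voxel.values[tgt]
    truth = np.asarray(truth, dtype=float).ravel()
    if len(truth) != len(tgt):
        raise InvalidInputError("truth length does not match the target shell")
    if order is None:
        order = np.arange(len(tgt))
    order = np.asarray(order, dtype=np.intp)
    g = sch.directions[tgt]
    b = np.full(len(tgt), sch.shell_bvalues[target_shell])

    rows = {}
    for n_pts in n_points_list:
        n_pts = int(n_pts)
        if n_pts > len(tgt):
            raise InvalidInputError(
                f"subset of {n_pts} points exceeds the {len(tgt)} available "
                f"on shell {target_shell}"
            )
        subset = tgt[order[:n_pts]]
        configs = {"none": subset}
        for s in support_shells:
            if s == target_shell:
                raise InvalidInputError("support shell equals the target shell")
            configs[f"shell_{s}"] = np.sort(np.concatenate([subset, sch.shell_members(s)]))
        row = {}
        for label, idx in configs.items():
            sub = VoxelSignal(voxel.values[idx], sch.subset(idx))
            est = predict(sub, hyper, g, b).mean
            row[label] = float(np.sqrt(np.mean((est - truth) ** 2)))
        rows[n_pts] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "n_points"
    return table
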