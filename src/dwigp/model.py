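"""Population-level Gaussian-process model of diffusion-weighted signals.

One set of covariance hyperparameters beta = (lambda, a, [ell], sigma_s^2)
is shared across voxels and estimated by maximising an objective summed over
a (sub)population of voxels — the type-II (marginal) likelihood by default,
or the leave-one-out CV / GPP criteria.  Optimisation is Nelder-Mead over
the unconstrained log-parameters, so positivity is automatic.

The API follows the Model/Results convention: :class:`DiffusionGP` holds the
data and model choice, ``fit()`` returns a :class:`DiffusionGPResults` that
carries the estimates, their uncertainties and the prediction machinery.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import gp
from .exceptions import InvalidInputError, NumericalConditioningError
from .gradients import GradientScheme
from .kernels import Hyperparameters, assemble_K

CRITERIA = ("ml", "cv", "gpp")

_NM_XATOL = 1e-4
_NM_FATOL = 1e-4
#: default voxel subsample used for fitting, following common practice of
#: estimating the hyperparameters from a random selection of ~1000 voxels
DEFAULT_FIT_VOXELS = 1000


def summed_objective(values, scheme, hyper, criterion: str = "ml") -> float:
    """Criterion summed over voxels at fixed hyperparameters.

    ``values`` is (V, n) aligned with the b0-free ``scheme``.  For "ml" this
    is the summed log marginal likelihood (equivalent to multiplying the
    per-voxel likelihoods); "cv" is the *negative* summed mean-squared LOO
    residual and "gpp" the summed mean LOO log predictive density, so every
    criterion is maximised.  Returns -inf where the kernel cannot be
    factorised or the criterion is non-finite.
    """
    if criterion not in CRITERIA:
        raise InvalidInputError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    try:
        kernel = assemble_K(scheme, hyper)
    except NumericalConditioningError:
        return -np.inf
    demeaned, _ = gp._demean(values, scheme)
    V, n = demeaned.shape
    with np.errstate(over="ignore", invalid="ignore"):
        if criterion == "ml":
            sol = kernel.solve(demeaned.T)
            quad = np.sum(demeaned.T * sol, axis=0)
            total = float(-0.5 * np.sum(quad) - 0.5 * V * kernel.log_det
                          - 0.5 * V * n * gp._LOG_2PI)
        else:
            A = kernel.inverse()
            d = np.diag(A)
            if np.any(d <= 0):
                return -np.inf
            alpha = A @ demeaned.T
            resid = alpha / d[:, None]
            if criterion == "cv":
                total = float(-np.sum(np.mean(resid**2, axis=0)))
            else:
                var = 1.0 / d
                dens = -0.5 * np.log(2.0 * np.pi * var)[:, None] - resid**2 / (2.0 * var[:, None])
                total = float(np.sum(np.mean(dens, axis=0)))
    return total if np.isfinite(total) else -np.inf


class DiffusionGP:
    """Gaussian-process model for a population of diffusion-weighted voxels.

    Parameters
    ----------
    signals : (V, n) array
        Per-voxel signal across the acquisition's volumes.  ``n`` may count
        all volumes of ``scheme`` (b0 entries are dropped internally) or only
        its diffusion-weighted volumes.
    scheme : GradientScheme
        The acquisition the signals align with.
    cov_model : {"spherical", "exponential"}
        Angular covariance family.

    Examples
    --------
    >>> model = DiffusionGP(signals, scheme, cov_model="spherical")
    >>> res = model.fit(criterion="ml", seed=0)
    >>> print(res.summary())
    """

    def __init__(self, signals, scheme: GradientScheme, cov_model: str = "spherical"):
        signals = np.atleast_2d(np.asarray(signals, dtype=float))
        if signals.shape[1] == len(scheme):
            signals = signals[:, scheme.dwi_indices]
        elif signals.shape[1] != len(scheme.dwi):
            raise InvalidInputError(
                f"signals have {signals.shape[1]} volumes; scheme has "
                f"{len(scheme)} ({len(scheme.dwi)} diffusion-weighted)"
            )
        self.endog = signals
        self.full_scheme = scheme
        self.scheme = scheme.dwi
        self.cov_model = cov_model
        # validate the model name early
        Hyperparameters(model=cov_model, lam=1.0, a=1.0,
                        sigma2=(1.0,) * max(scheme.n_shells, 1),
                        ell=1.0 if scheme.n_shells > 1 else None)

    @classmethod
    def from_dataset(cls, bundle, cov_model: str = "spherical") -> "DiffusionGP":
        """Build from an :class:`~dwigp.io.DatasetBundle` (masked voxels only)."""
        model = cls(bundle.voxel_matrix(), bundle.scheme, cov_model=cov_model)
        model._bundle = bundle
        return model

    # -- voxel access ------------------------------------------------------

    @property
    def n_voxels(self) -> int:
        return self.endog.shape[0]

    def voxel(self, index: int) -> gp.VoxelSignal:
        return gp.VoxelSignal(self.endog[index], self.scheme)

    def default_hyperparameters(self) -> Hyperparameters:
        """Data-driven starting point: lam from the demeaned signal variance."""
        demeaned, _ = gp._demean(self.endog, self.scheme)
        lam = float(np.mean(demeaned**2))
        if lam <= 0:
            lam = 1.0
        S = self.scheme.n_shells
        return Hyperparameters(
            model=self.cov_model, lam=lam, a=1.0,
            sigma2=(0.1 * lam,) * S, ell=1.0 if S > 1 else None,
        )

    def objective_from_vector(self, u: np.ndarray, criterion: str = "ml",
                              voxel_indices: np.ndarray | None = None) -> float:
        """Summed objective at unconstrained log-parameters ``u``."""
        try:
            hyper = Hyperparameters.from_vector(u, self.cov_model, self.scheme.n_shells)
        except (ValueError, OverflowError):
            return -np.inf
        values = self.endog if voxel_indices is None else self.endog[voxel_indices]
        return summed_objective(values, self.scheme, hyper, criterion)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        criterion: str = "ml",
        init: Hyperparameters | None = None,
        n_voxels: int | None = DEFAULT_FIT_VOXELS,
        n_restarts: int = 0,
        seed: int = 0,
        xatol: float = _NM_XATOL,
        fatol: float = _NM_FATOL,
        maxfev: int | None = None,
    ) -> "DiffusionGPResults":
        """Estimate the hyperparameters by Nelder-Mead over log-parameters.

        ``n_voxels`` caps the fitting subpopulation (seeded uniform sample
        without replacement; None uses every voxel).  ``n_restarts`` adds
        extra starts whose log-parameters are perturbed by seeded normal
        offsets (log-normal factors on the natural scale); the best final
        objective wins.  Deterministic given ``seed`` and ``init``.
        """
        if criterion not in CRITERIA:
            raise InvalidInputError(
                f"unknown criterion {criterion!r}; expected one of {CRITERIA}"
            )
        rng = np.random.default_rng(seed)
        if n_voxels is not None and n_voxels < self.n_voxels:
            voxel_indices = np.sort(rng.choice(self.n_voxels, size=n_voxels, replace=False))
        else:
            voxel_indices = np.arange(self.n_voxels)
        u0 = (init or self.default_hyperparameters()).to_vector()
        d = len(u0)
        if maxfev is None:
            maxfev = 200 * d

        n_eval = 0
        trace: list[float] = []

        def negative(u):
            nonlocal n_eval
            n_eval += 1
            val = self.objective_from_vector(u, criterion, voxel_indices)
            best = val if not trace else max(trace[-1], val)
            trace.append(best)
            return -val

        starts = [u0] + [u0 + rng.normal(0.0, 0.3, size=d) for _ in range(n_restarts)]
        best_res = None
        for u_start in starts:
            res = minimize(negative, u_start, method="Nelder-Mead",
                           options={"xatol": xatol, "fatol": fatol, "maxfev": maxfev})
            if best_res is None or res.fun < best_res.fun:
                best_res = res
        converged = bool(best_res.success)
        if not converged:
            warnings.warn("Nelder-Mead did not report convergence; returning "
                          "the best point found", stacklevel=2)
        hyper = Hyperparameters.from_vector(best_res.x, self.cov_model,
                                            self.scheme.n_shells)
        return DiffusionGPResults(
            model=self, params=hyper, criterion=criterion,
            objective_value=float(-best_res.fun), converged=converged,
            n_evaluations=n_eval, trace=np.asarray(trace),
            voxel_indices=voxel_indices, seed=seed,
        )


@dataclass
class DiffusionGPResults:
    """Fitted hyperparameters plus the GP prediction machinery.

    ``objective_value`` re-evaluates to the criterion at ``params`` on the
    fitting voxels; ``trace`` is the best objective after each evaluation
    (non-decreasing).
    """

    model: DiffusionGP
    params: Hyperparameters
    criterion: str
    objective_value: float
    converged: bool
    n_evaluations: int
    trace: np.ndarray
    voxel_indices: np.ndarray
    seed: int
    _kernel: object = field(default=None, repr=False)

    # -- kernel reuse ------------------------------------------------------

    @property
    def kernel(self):
        """The factorised kernel for (scheme, params), computed once."""
        if self._kernel is None:
            self._kernel = assemble_K(self.model.scheme, self.params)
        return self._kernel

    # -- prediction --------------------------------------------------------

    def predict(self, query_directions, query_bvalues=None, voxels=None) -> gp.Prediction:
        """Predict at arbitrary (direction, b-value) points.

        ``voxels`` selects voxel rows (default: all); the mean is (V, m) and
        the variance (m,), shared by construction across voxels.
        """
        values = self.model.endog if voxels is None else np.atleast_2d(self.model.endog[voxels])
        return gp.predict(values, self.params, query_directions, query_bvalues,
                          scheme=self.model.scheme, kernel=self.kernel)

    def predict_volume(self, target_index: int, mode: str = "interpolation") -> np.ndarray:
        """Predict one acquired volume for every voxel (smoothing keeps the
        observed volume in the training set; interpolation drops it)."""
        if mode not in ("smoothing", "interpolation"):
            raise InvalidInputError("mode must be 'smoothing' or 'interpolation'")
        signals = np.empty((self.model.n_voxels, len(self.model.full_scheme)))
        signals[:, self.model.full_scheme.dwi_indices] = self.model.endog
        signals[:, self.model.full_scheme.is_b0] = 0.0
        return gp.predict_volume(signals, self.model.full_scheme, self.params,
                                 target_index, include_self=(mode == "smoothing"))

    def sample_prior(self, n_draws: int, seed: int) -> np.ndarray:
        return gp.sample_prior(self.model.scheme, self.params, n_draws, seed)

    def loo_scores(self, voxels=None) -> np.ndarray:
        """Per-voxel (cv, gpp) scores as an (V, 2) array."""
        idx = np.arange(self.model.n_voxels) if voxels is None else np.atleast_1d(voxels)
        return np.array([gp.loo_criteria(self.model.voxel(i), self.kernel) for i in idx])

    def shell_subsample(self, voxel: int, target_shell: int, n_points_list,
                        support_shells, truth=None, order=None):
        return gp.shell_subsample_experiment(
            self.model.voxel(voxel), self.params, target_shell,
            n_points_list, support_shells, truth=truth, order=order,
        )

    # -- uncertainties and summary ----------------------------------------

    @property
    def param_names(self) -> list:
        names = ["log(lambda)", "log(a)"]
        if self.params.ell is not None:
            names.append("log(ell)")
        names += [f"log(sigma2[{s}])" for s in range(self.params.n_shells)]
        return names

    def hessian(self, rel_step: float = 1e-3) -> np.ndarray:
        """Finite-difference Hessian of the summed ML objective at the optimum
        (unconstrained coordinates)."""
        from .evidence import finite_difference_hessian

        def f(u):
            return self.model.objective_from_vector(u, "ml", self.voxel_indices)

        return finite_difference_hessian(f, self.params.to_vector(), rel_step)

    @property
    def bse(self) -> np.ndarray:
        """Asymptotic standard errors of the log-parameters from the inverse
        negative Hessian (nan where the curvature is not negative definite)."""
        H = self.hessian()
        try:
            cov = np.linalg.inv(-H)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            return np.full(len(self.param_names), np.nan)
        return np.where(np.diag(cov) > 0, se, np.nan)

    def log_evidence(self, rel_step: float = 1e-3):
        """Laplace-approximated log model evidence (see :mod:`dwigp.evidence`)."""
        from .evidence import laplace_log_evidence
        return laplace_log_evidence(self, rel_step=rel_step)

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of statsmodels results."""
        p = self.params
        lines = [
            "Diffusion GP hyperparameter fit",
            "=" * 46,
            f"angular model:      {p.model}",
            f"criterion:          {self.criterion}",
            f"n voxels (fit):     {len(self.voxel_indices)}",
            f"n measurements:     {len(self.model.scheme)}"
            f" on {self.model.scheme.n_shells} shell(s)",
            f"objective at opt:   {self.objective_value:.4f}",
            f"converged:          {self.converged}"
            f"   (evaluations: {self.n_evaluations})",
            "-" * 46,
            f"{'parameter':<14}{'estimate':>14}{'se(log)':>12}",
        ]
        se = self.bse
        values = [p.lam, p.a] + ([p.ell] if p.ell is not None else []) + list(p.sigma2)
        names = ["lambda", "a (rad)"] + (["ell"] if p.ell is not None else []) \
            + [f"sigma2[{s}]" for s in range(p.n_shells)]
        for name, v, s in zip(names, values, se):
            lines.append(f"{name:<14}{v:>14.6g}{s:>12.3g}")
        lines.append("=" * 46)
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_voxel_fit(self, voxel: int, ax=None):
        """Observed signal of one voxel against the GP smoothing curve.

        Measurements are ordered by axial angle from the voxel's minimum
        (the putative fibre direction), which unfolds the spherical profile
        into a readable 1-D plot; the shaded band is +/- 2 predictive sd.
        """
        import matplotlib.pyplot as plt

        vox = self.model.voxel(voxel)
        sch = vox.scheme
        ref = sch.directions[int(np.argmin(vox.values))]
        angle = np.arccos(np.clip(np.abs(sch.directions @ ref), 0.0, 1.0))
        order = np.argsort(angle)
        pred = gp.predict(vox, self.params, sch.directions[order],
                          sch.shell_bvalues[sch.shell_ids[order]],
                          kernel=self.kernel)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(angle[order], vox.values[order], "k.", label="observed")
        ax.plot(angle[order], pred.mean, "C0-", label="GP mean")
        sd = np.sqrt(pred.variance)
        ax.fill_between(angle[order], pred.mean - 2 * sd, pred.mean + 2 * sd,
                        color="C0", alpha=0.2, label="±2 sd")
        ax.set_xlabel("axial angle from signal minimum (rad)")
        ax.set_ylabel("signal")
        ax.legend(frameon=False)
        return ax

    def plot_trace(self, ax=None):
        """Best objective value after each Nelder-Mead evaluation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        finite = np.isfinite(self.trace)
        ax.plot(np.flatnonzero(finite), self.trace[finite])
        ax.set_xlabel("objective evaluation")
        ax.set_ylabel(f"best summed {self.criterion} objective")
        return ax

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update({
            "criterion": self.criterion,
            "objective": self.objective_value,
            "converged": self.converged,
            "n_voxels": int(len(self.voxel_indices)),
            "seed": int(self.seed),
        })
        return d

    def save_params(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(_round_floats(self.to_dict()), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _round_floats(obj, ndigits: int = 12):
    """Fixed-precision floats so serialised reports are byte-reproducible."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj
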