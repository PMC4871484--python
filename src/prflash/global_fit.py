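"""Global multi-exponential analysis by variable projection.

All probe wavelengths are fitted simultaneously with a shared set of
lifetimes: the model is

    DeltaA(lambda, t) = sum_i A_i(lambda) * exp(-t / tau_i)

where the per-wavelength amplitudes A_i(lambda) form the decay-associated
spectra (DAS).  For any trial lifetime set the amplitudes are the solution of
a linear least-squares problem, so the nonlinear search runs only over the
lifetimes (variable projection), parameterized as log tau to enforce
positivity.  The default model carries no additive offset, since the
photocycle fully recovers the ground state; an offset column and a
1/sqrt(block size) weighting for log-reduced data are available behind flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .trace_reduction import ReducedTraceSet

__all__ = ["GlobalFitResult", "fit_global", "reconstruct_initial_amplitude",
           "select_n_exponentials"]

_MULTISTART_SEED = 20160517  # fixed: multistart draws are part of the method
_N_STARTS = 5
_FTOL = 1e-10
_MAX_ITER = 500


@dataclass
class GlobalFitResult:
    """Shared lifetimes, decay-associated spectra and fit diagnostics."""

    lifetimes: np.ndarray  # (n_exp,) seconds, ascending
    das: np.ndarray  # (n_exp, n_wavelengths) OD
    wavelengths: np.ndarray  # nm
    residual_rms: float  # OD
    n_exponentials: int
    converged: bool
    tau_relative_stderr: np.ndarray = field(default_factory=lambda: np.array([]))
    offset: np.ndarray | None = None  # per-wavelength constant, if fitted

    def __post_init__(self) -> None:
        if np.any(self.lifetimes <= 0):
            raise ValueError("lifetimes must be positive")
        if np.any(np.diff(self.lifetimes) < 0):
            raise ValueError("lifetimes must be ascending")
        if self.das.shape != (self.n_exponentials, self.wavelengths.size):
            raise ValueError("das must be (n_exponentials, n_wavelengths)")


def _design_matrix(times: np.ndarray, taus: np.ndarray, offset: bool) -> np.ndarray:
    E = np.exp(-times[:, None] / taus[None, :])
    if offset:
        E = np.hstack([E, np.ones((times.size, 1))])
    return E


def _projected_residual(log_tau, times, data_T, weights, offset):
    """Residual matrix after eliminating amplitudes by linear least squares.

    ``data_T`` is (n_times, n_wavelengths); weights (n_times,) or None.
    Returns (residuals flattened, amplitudes (n_cols, n_wavelengths)).
    """
    E = _design_matrix(times, np.exp(log_tau), offset)
    if weights is not None:
        Ew, dw = E * weights[:, None], data_T * weights[:, None]
    else:
        Ew, dw = E, data_T
    amps, *_ = np.linalg.lstsq(Ew, dw, rcond=None)
    return (Ew @ amps - dw).ravel(), amps


def _default_starts(times: np.ndarray, n_exp: int) -> list[np.ndarray]:
    """One deterministic log-spaced start plus seeded log-uniform draws.

    Starts span [2 * min spacing, 2 * max time], the lifetime range the data
    can constrain.
    """
    lo = np.log(2.0 * np.min(np.diff(times)))
    hi = np.log(2.0 * times[-1])
    starts = [np.linspace(lo + 0.15 * (hi - lo), hi - 0.15 * (hi - lo), n_exp)]
    rng = np.random.default_rng(_MULTISTART_SEED)
    for _ in range(_N_STARTS - 1):
        starts.append(np.sort(rng.uniform(lo, hi, size=n_exp)))
    return starts


def fit_global(
    data: ReducedTraceSet,
    n_exponentials: int,
    init=None,
    offset: bool = False,
    weighting: str | None = None,
) -> GlobalFitResult:
    """Fit a shared-lifetime exponential sum to all wavelengths at once.

    Parameters
    ----------
    data : ReducedTraceSet
        Log-reduced (optionally merged) trace set; times in seconds.
    n_exponentials : int
        Number of exponential components (shared lifetimes).
    init : sequence of float, optional
        Initial lifetimes in seconds.  When absent, a multistart over a
        log-spaced/log-uniform grid is used and the best local optimum kept.
    offset : bool
        Fit an additive per-wavelength constant (off by default: a fully
        recovering photocycle decays to zero).
    weighting : {"block", None}
        "block" weights each point by sqrt(block size) (inverse of the
        block-averaged noise sd); requires reduction provenance.
    """
    if n_exponentials < 1:
        raise ValueError("n_exponentials must be >= 1")
    times, data_T = data.times, data.delta_A.T
    n_params = n_exponentials + (1 if offset else 0)
    if times.size <= n_params:
        raise ValueError("more fit components than time points")

    if weighting is None:
        weights = None
    elif weighting == "block":
        sizes = data.block_sizes
        if sizes.size != times.size:
            raise ValueError("block weighting requires reduction provenance")
        weights = np.sqrt(sizes.astype(float))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    if init is not None:
        init = np.asarray(init, dtype=float)
        if init.size != n_exponentials or np.any(init <= 0):
            raise ValueError("init must give one positive lifetime per component")
        starts = [np.log(init)]
    else:
        starts = _default_starts(times, n_exponentials)

    best = None
    for x0 in starts:
        sol = least_squares(
            lambda x: _projected_residual(x, times, data_T, weights, offset)[0],
            x0,
            method="lm",
            ftol=_FTOL,
            xtol=1e-12,
            max_nfev=_MAX_ITER * (n_exponentials + 1),
        )
        if best is None or sol.cost < best.cost:
            best = sol

    converged = bool(best.status > 0)
    resid, amps = _projected_residual(best.x, times, data_T, weights, offset)
    taus = np.exp(best.x)

    # relative standard error of each tau from the projected-problem Jacobian
    rel_se = np.full(n_exponentials, np.nan)
    try:
        dof = max(resid.size - n_exponentials * (1 + data.wavelengths.size), 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        rel_se = np.sqrt(np.diag(cov))  # se of log tau == relative se of tau
    except np.linalg.LinAlgError:
        pass

    order = np.argsort(taus)
    das = amps[:n_exponentials][order]
    off = amps[n_exponentials] if offset else None
    model_resid = data.delta_A - _design_matrix(times, taus, offset).dot(amps).T
    return GlobalFitResult(
        lifetimes=taus[order],
        das=das,
        wavelengths=data.wavelengths.copy(),
        residual_rms=float(np.sqrt(np.mean(model_resid**2))),
        n_exponentials=n_exponentials,
        converged=converged,
        tau_relative_stderr=rel_se[order],
        offset=off,
    )


def reconstruct_initial_amplitude(result: GlobalFitResult, wavelength: float) -> float:
    """Back-extrapolated DeltaA at t -> 0+ for one wavelength: sum_i A_i(lambda)."""
    idx = np.nonzero(np.isclose(result.wavelengths, wavelength))[0]
    if idx.size == 0:
        raise KeyError(f"wavelength {wavelength} nm not in the fitted set")
    total = float(result.das[:, idx[0]].sum())
    if result.offset is not None:
        total += float(result.offset[idx[0]])
    return total


def select_n_exponentials(
    data: ReducedTraceSet,
    max_n: int,
    improvement_threshold: float = 0.05,
    **fit_kwargs,
):
    """Smallest component count beyond which the residual stops improving.

    Fits n = 1 ... max_n and stops when adding a component improves the
    residual rms by less than ``improvement_threshold`` (fractional); returns
    ``(n_selected, report)`` where the report lists residual_rms per n.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    report = []
    prev_rms, selected = None, max_n
    for n in range(1, max_n + 1):
        res = fit_global(data, n, **fit_kwargs)
        report.append({"n": n, "residual_rms": res.residual_rms,
                       "converged": res.converged})
        if prev_rms is not None and (prev_rms - res.residual_rms) < improvement_threshold * prev_rms:
            selected = n - 1
            break
        prev_rms = res.residual_rms
    return selected, report
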