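"""Shared non-linear least-squares plumbing: AICc, covariance, multistart."""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

__all__ = ["aicc", "covariance_from_jacobian", "run_multistart", "FitFailure"]


class FitFailure(RuntimeError):
    """Raised when every optimisation start fails to converge."""


def aicc(ssr: float, n_points: int, n_params: int) -> float:
    """Small-sample corrected Akaike criterion for Gaussian residuals.

    ``n_params`` counts model parameters; the residual variance adds one more.
    Returns +inf when the correction denominator is not positive (model too
    rich for the data), which removes such fits from any argmin selection.
    """
    k = n_params + 1
    if n_points - k - 1 <= 0:
        return np.inf
    ssr = max(float(ssr), np.finfo(float).tiny)
    return n_points * np.log(ssr / n_points) + 2 * k + 2 * k * (k + 1) / (n_points - k - 1)


def covariance_from_jacobian(jac: np.ndarray, ssr: float, n_points: int) -> np.ndarray:
    """Parameter covariance s²·(JᵀJ)⁻¹ with a pseudo-inverse fallback.

    Near-singular JᵀJ (parameter ridges) yields very large variances rather
    than an exception, so confidence intervals honestly reflect
    non-identifiability.
    """
    n_params = jac.shape[1]
    dof = max(n_points - n_params, 1)
    s2 = ssr / dof
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj, rcond=1e-12)
    return s2 * cov


def run_multistart(residual, starts, bounds=None, **ls_kwargs):
    """Run ``scipy.optimize.least_squares`` from several starts, keep the best.

    Parameters
    ----------
    residual : callable(theta) -> residual vector
    starts : iterable of parameter vectors
    bounds : (lb, ub) or None

    Returns the best ``OptimizeResult``; raises :class:`FitFailure` if no
    start converges.
    """
    best = None
    kw = dict(method="trf", x0=None)
    kw.update(ls_kwargs)
    kw.pop("x0")
    if bounds is not None:
        kw["bounds"] = bounds
    for x0 in starts:
        try:
            res = least_squares(residual, np.asarray(x0, dtype=float), **kw)
        except Exception:
            continue
        if not np.all(np.isfinite(res.fun)):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailure("no optimisation start converged")
    return best
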