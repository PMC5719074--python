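"""Two-state ("open"/"closed") concerted binding model for porphyrin–20S kinetics.

The 20S core particle interconverts between a closed (gate-shut, dominant in
the apo enzyme) and an open conformation.  A cluster of ``n`` equivalent
porphyrin sites binds with per-site association constant ``K_open`` to the
open and ``K_closed`` to the closed conformation; the conformational
equilibrium at zero ligand is ``L = [open]/[closed]``.  Under the concerted
(all-sites-switch-together) assumption the fraction of particles in the open
conformation at free ligand concentration ``x`` is

    f_open(x) = L·(1 + K_open·x)^n / [ (1 + K_closed·x)^n + L·(1 + K_open·x)^n ]

The observed pseudo-first-order binding rate constant is the
population-weighted association rate plus dissociation,

    k_obs(x) = ( k_on_closed·f_closed + k_on_open·f_open ) · x + k_off

which reduces to the classical bimolecular form ``k_obs = k_on·x + k_off``
when only one conformation exists (open-locked mutant) or when the two
states are kinetically indistinguishable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._fitting import aicc, covariance_from_jacobian, run_multistart
from .params import TwoStateParams

__all__ = [
    "KobsSeries",
    "PopulationCurve",
    "TwoStateBindingModel",
    "ModeComparison",
    "NSweepResult",
    "ConsistencyReport",
    "populations",
    "kobs_model",
    "fit_kobs",
    "compare_modes",
    "population_curves",
    "consistency_report",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class KobsSeries:
    """Observed rate constants vs ligand concentration for one kinetic phase.

    ``x`` in M, ``k_obs`` in s^-1; ``se`` optional standard errors.
    """

    x: np.ndarray
    k_obs: np.ndarray
    se: Optional[np.ndarray] = None
    phase: str = ""
    system: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.k_obs = np.asarray(self.k_obs, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
        if self.x.shape != self.k_obs.shape:
            raise ValueError("x and k_obs must have the same shape")
        if np.any(self.x <= 0):
            raise ValueError("ligand concentrations must be > 0")
        if np.any(self.k_obs <= 0):
            raise ValueError("k_obs values must be > 0")

    def __len__(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        d = {"x_M": self.x, "kobs_per_s": self.k_obs}
        if self.se is not None:
            d["se"] = self.se
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "KobsSeries":
        se = df["se"].to_numpy() if "se" in df.columns else None
        return cls(df["x_M"].to_numpy(), df["kobs_per_s"].to_numpy(), se=se, **kw)


@dataclass
class PopulationCurve:
    """Open/closed population fractions over a ligand concentration grid."""

    x: np.ndarray
    f_open: np.ndarray
    f_closed: np.ndarray
    crossover: Optional[float] = None  # x where f_open = 0.5, if inside the grid

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_M": self.x, "f_open": self.f_open, "f_closed": self.f_closed}
        )


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------


def populations(x, p: TwoStateParams):
    """Open/closed fractions ``(f_closed, f_open)`` at ligand concentration ``x``.

    Evaluated in log space (``log1p``/logistic) so it is overflow-safe for
    arbitrarily large ``x``.  Ordering of the return matches the convention
    that the closed state is listed first (it dominates the apo enzyme).
    """
    if p.is_bimolecular:
        raise ValueError("populations requires a full two-state parameter set")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    n = p.n_sites
    log_ratio = (
        np.log(p.L)
        + n * np.log1p(p.K_open * x)
        - n * np.log1p(p.K_closed * x)
    )
    f_open = expit(log_ratio)
    return 1.0 - f_open, f_open


def kobs_model(x, p: TwoStateParams, mode: Optional[str] = None):
    """Observed pseudo-first-order rate constant at ligand concentration ``x``.

    ``mode`` is ``"bimolecular"`` or ``"cooperative"``; by default it follows
    the parameter set (bimolecular when no closed-state branch is present).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    if mode is None:
        mode = "bimolecular" if p.is_bimolecular else "cooperative"
    if mode == "bimolecular":
        return p.k_on_open * x + p.k_off
    if mode == "cooperative":
        if p.is_bimolecular:
            raise ValueError("cooperative mode requires closed-state parameters")
        f_closed, f_open = populations(x, p)
        return (p.k_on_closed * f_closed + p.k_on_open * f_open) * x + p.k_off
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

# log10 bounds used for all fitted parameters
_LOG_BOUNDS = {
    "k_on_open": (0.0, 10.0),
    "k_on_closed": (-2.0, 10.0),
    "k_off": (-4.0, 4.0),
    "K_open": (0.0, 12.0),
    "K_closed": (-2.0, 12.0),
    "L": (-12.0, 3.0),
}

_COOP_NAMES = ("k_on_open", "k_on_closed", "k_off", "K_open", "K_closed", "L")
_BIMOL_NAMES = ("k_on_open", "k_off")


class TwoStateBindingModel(BaseEstimator, RegressorMixin):
    """Fit k_obs(x) under the bimolecular or cooperative two-state law.

    Parameters
    ----------
    mode : {"cooperative", "bimolecular"}
        Which observed-rate law to fit.
    n_sites : int
        Number of sites per cluster, held fixed during the fit (a small
        integer, never a continuous exponent).
    weighting : {"relative", "absolute"}
        Residual weighting when no per-point weights are given.  Rate
        constants span decades with roughly constant relative error, so the
        default minimises relative residuals; "absolute" is plain SSR.
        Explicit ``sample_weight`` (e.g. 1/SE²) overrides this.
    n_starts : int
        Number of multistart initialisations (log-spaced/log-uniform).
    random_state : int
        Seed for the multistart sampler.

    Attributes
    ----------
    params_ : TwoStateParams
        Fitted parameter set.
    se_log_, ci95_ : dict
        Standard errors of the natural-log parameters and 95% confidence
        intervals on the natural scale (ridge-shaped likelihoods yield very
        wide intervals).
    ssr_, aicc_, n_points_ : float / int
    """

    def __init__(self, mode: str = "cooperative", n_sites: int = 3,
                 weighting: str = "relative", n_starts: int = 16,
                 random_state: int = 0):
        self.mode = mode
        self.n_sites = n_sites
        self.weighting = weighting
        self.n_starts = n_starts
        self.random_state = random_state

    # -- internal -----------------------------------------------------------

    def _theta_to_params(self, theta: np.ndarray) -> TwoStateParams:
        vals = dict(zip(self._names_, np.exp(theta)))
        if self.mode == "bimolecular":
            return TwoStateParams(
                k_on_open=vals["k_on_open"], k_off=vals["k_off"], label="fit"
            )
        return TwoStateParams(
            k_on_open=vals["k_on_open"],
            k_on_closed=vals["k_on_closed"],
            k_off=vals["k_off"],
            K_open=vals["K_open"],
            K_closed=vals["K_closed"],
            L=vals["L"],
            n_sites=self.n_sites,
            label="fit",
        )

    def _starts(self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator):
        lo, hi = self._bounds_
        # heuristic start from the data shape
        k_off0 = max(float(np.min(y)) * 0.9, 1e-4)
        k_on0 = max((float(np.max(y)) - k_off0) / float(np.max(x)), 1e-2)
        if self.mode == "bimolecular":
            heur = np.log([k_on0, k_off0])
        else:
            x_mid = float(np.sqrt(np.min(x) * np.max(x)))
            L0 = 1e-5
            K_open0 = L0 ** (-1.0 / self.n_sites) / x_mid
            heur = np.log(
                [k_on0, max(k_on0 * 1e-4, 1e-2), k_off0, K_open0, 1.0 / np.max(x), L0]
            )
        heur = np.clip(heur, lo + 1e-6, hi - 1e-6)
        starts = [heur]
        for _ in range(max(self.n_starts - 1, 0)):
            starts.append(rng.uniform(lo, hi))
        return starts

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y, sample_weight=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("X and y length mismatch")
        if np.any(x <= 0):
            raise ValueError("ligand concentrations must be > 0")
        if self.mode not in ("cooperative", "bimolecular"):
            raise ValueError(f"unknown mode {self.mode!r}")
        min_pts = 5 if self.mode == "cooperative" else 3
        if x.size < min_pts:
            raise ValueError(
                f"{self.mode} fit needs at least {min_pts} points, got {x.size}"
            )
        if sample_weight is not None:
            w = np.sqrt(np.asarray(sample_weight, dtype=float).reshape(-1))
        elif self.weighting == "relative":
            w = 1.0 / y
        elif self.weighting == "absolute":
            w = np.ones_like(y)
        else:
            raise ValueError(f"unknown weighting {self.weighting!r}")

        self._names_ = _BIMOL_NAMES if self.mode == "bimolecular" else _COOP_NAMES
        lb = np.array([_LOG_BOUNDS[n][0] for n in self._names_]) * np.log(10.0)
        ub = np.array([_LOG_BOUNDS[n][1] for n in self._names_]) * np.log(10.0)
        self._bounds_ = (lb, ub)

        def residual(theta):
            p = self._theta_to_params(theta)
            return w * (kobs_model(x, p, mode=self.mode) - y)

        rng = np.random.default_rng(self.random_state)
        res = run_multistart(
            residual, self._starts(x, y, rng), bounds=(lb, ub), xtol=1e-12, ftol=1e-12
        )

        self.theta_ = res.x
        self.params_ = self._theta_to_params(res.x)
        self.ssr_ = float(2 * res.cost)
        self.n_points_ = x.size
        self.aicc_ = aicc(self.ssr_, x.size, len(self._names_))
        cov = covariance_from_jacobian(res.jac, self.ssr_, x.size)
        self.cov_log_ = cov
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        self.se_log_ = dict(zip(self._names_, se))
        # Student-t critical value at the residual degrees of freedom
        dof = x.size - len(self._names_)
        tcrit = float(t_dist.ppf(0.975, dof)) if dof > 0 else np.inf
        self.ci95_ = {
            n: (float(np.exp(np.clip(t - tcrit * s, -700, 700))),
                float(np.exp(np.clip(t + tcrit * s, -700, 700))))
            for n, t, s in zip(self._names_, res.x, se)
        }
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return kobs_model(x, self.params_, mode=self.mode)


@dataclass
class NSweepResult:
    fits: dict[int, TwoStateBindingModel]
    aicc: dict[int, float]
    selected_n: int


def fit_kobs(series: KobsSeries, mode: str = "cooperative",
             n_fixed=3, n_starts: int = 16, random_state: int = 0):
    """Fit a k_obs series; ``n_fixed`` may be an int or a sweep of ints.

    With a sweep, one fit is run per candidate site number and the AICc-best
    is selected (all candidates share the same parameter count, so this is a
    pure goodness-of-fit comparison).
    """
    weights = None if series.se is None else 1.0 / series.se**2
    if np.isscalar(n_fixed):
        est = TwoStateBindingModel(mode=mode, n_sites=int(n_fixed),
                                   n_starts=n_starts, random_state=random_state)
        est.fit(series.x, series.k_obs, sample_weight=weights)
        return est
    fits, crits = {}, {}
    for n in n_fixed:
        est = TwoStateBindingModel(mode=mode, n_sites=int(n),
                                   n_starts=n_starts, random_state=random_state)
        est.fit(series.x, series.k_obs, sample_weight=weights)
        fits[int(n)] = est
        crits[int(n)] = est.aicc_
    best = min(crits, key=crits.get)
    return NSweepResult(fits=fits, aicc=crits, selected_n=best)


@dataclass
class ModeComparison:
    selected: Optional[str]
    fits: dict[str, TwoStateBindingModel]
    aicc: dict[str, float]
    f_statistic: Optional[float]
    f_pvalue: Optional[float]
    reason: str = ""


def compare_modes(series: KobsSeries, n_sites: int = 3,
                  n_starts: int = 16, random_state: int = 0) -> ModeComparison:
    """Fit both rate laws and select by AICc.

    The straight-line (bimolecular) model is also tested against the
    cooperative one with an extra-sum-of-squares F-test, reported as a
    linearity diagnostic.  Selection is refused (``selected=None``) when
    either model lacks the degrees of freedom for a finite AICc, e.g. very
    short series; both fits are still returned.
    """
    from scipy.stats import f as f_dist

    fits, crits = {}, {}
    for mode in ("bimolecular", "cooperative"):
        try:
            fits[mode] = fit_kobs(series, mode=mode, n_fixed=n_sites,
                                  n_starts=n_starts, random_state=random_state)
            crits[mode] = fits[mode].aicc_
        except ValueError as exc:
            crits[mode] = np.inf
            fits[mode] = None
            reason = str(exc)

    f_stat = f_p = None
    fb, fc = fits.get("bimolecular"), fits.get("cooperative")
    if fb is not None and fc is not None:
        df1 = 4  # extra parameters of the cooperative law
        df2 = len(series) - 6
        if df2 > 0 and fc.ssr_ > 0:
            f_stat = ((fb.ssr_ - fc.ssr_) / df1) / (fc.ssr_ / df2)
            f_p = float(f_dist.sf(max(f_stat, 0.0), df1, df2))

    if not all(np.isfinite(v) for v in crits.values()):
        return ModeComparison(None, fits, crits, f_stat, f_p,
                              reason="insufficient points for model selection")
    selected = min(crits, key=crits.get)
    return ModeComparison(selected, fits, crits, f_stat, f_p)


def population_curves(p: TwoStateParams, x_grid) -> PopulationCurve:
    """Tabulate open/closed fractions and locate the 50/50 crossover.

    The crossover (``f_open = 0.5``) is found by a bracketed root solve and
    reported only if it falls inside the grid.
    """
    x = np.asarray(x_grid, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x grid must be > 0")
    f_closed, f_open = populations(x, p)
    crossover = None
    g = f_open - 0.5
    if g.min() < 0 < g.max():
        # bracket between adjacent grid points with a sign change
        i = int(np.argmax(np.diff(np.sign(g)) != 0))
        crossover = float(
            brentq(lambda xv: populations(xv, p)[1] - 0.5, x[i], x[i + 1])
        )
    return PopulationCurve(x=x, f_open=f_open, f_closed=f_closed, crossover=crossover)


@dataclass
class ConsistencyReport:
    """Detailed-balance diagnostics: kinetic vs equilibrium constants.

    For a single-step binding reaction the association equilibrium constant
    should equal k_on/k_off; ``ratio_open`` is (k_on_open/k_off)/K_open and
    analogously for the closed state.  Each branch is flagged separately
    when its ratio departs from 1 by more than the fold limit (a single
    shared k_off can genuinely satisfy detailed balance in one conformation
    and not the other if the reported constants are inconsistent).
    """

    ratio_open: Optional[float]
    ratio_closed: Optional[float]
    flagged_open: bool
    flagged_closed: bool

    @property
    def flagged(self) -> bool:
        return self.flagged_open or self.flagged_closed

    def to_text(self) -> str:
        lines = ["detailed-balance check (kinetic/equilibrium ratio, 1 = exact):"]
        if self.ratio_open is not None:
            lines.append(f"  open state:   k_on/k_off vs K_open  -> "
                         f"{self.ratio_open:.3g} (flag: {self.flagged_open})")
        if self.ratio_closed is not None:
            lines.append(f"  closed state: k_on/k_off vs K_closed -> "
                         f"{self.ratio_closed:.3g} (flag: {self.flagged_closed})")
        return "\n".join(lines)


def consistency_report(p: TwoStateParams, fold_limit: float = 3.0) -> ConsistencyReport:
    def off(r):
        return r is not None and (r > fold_limit or r < 1.0 / fold_limit)

    ratio_open = ratio_closed = None
    if p.K_open is not None:
        ratio_open = (p.k_on_open / p.k_off) / p.K_open
    if p.K_closed is not None and p.k_on_closed is not None:
        ratio_closed = (p.k_on_closed / p.k_off) / p.K_closed
    return ConsistencyReport(ratio_open, ratio_closed, off(ratio_open),
                             off(ratio_closed))
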