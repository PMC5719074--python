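"""Multi-exponential decomposition of stopped-flow absorbance progress curves.

A relaxation trace recorded at the porphyrin Soret band (421 nm in the
reference experiments) is modelled as a sum of exponential phases on a
constant plateau,

    A(t) = A_inf + sum_i a_i · exp(-k_i · t)

Sign convention: a phase with negative amplitude relaxes *upward* toward the
plateau and is labelled hyperchromic (absorbance increase on binding); a
positive amplitude relaxes downward and is hypochromic.  Phases are reported
in temporal order, i.e. by descending observed rate constant ``k_i``.

Fitting uses variable projection: the non-linear search runs over the log
rates only, with the amplitudes and plateau solved exactly by linear least
squares at every step.  The number of phases is chosen by AICc with a
pruning rule: a candidate fit is excluded from selection when any amplitude
is indistinguishable from zero (|a| < 2·SE) or when two rates are nearly
degenerate, which prevents overfitting a two-phase trace with three phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._fitting import aicc, covariance_from_jacobian, FitFailure
from .gating import KobsSeries

__all__ = [
    "ProgressCurve",
    "ExpFit",
    "Phase",
    "ExponentialRelaxation",
    "PhaseSelection",
    "fit_exponentials",
    "select_n_phases",
    "classify_phases",
    "collect_kobs",
]

RATE_DEGENERACY_RATIO = 1.05


@dataclass
class ProgressCurve:
    """One absorbance trace: time (s), absorbance (AU), and metadata."""

    t: np.ndarray
    A: np.ndarray
    wavelength_nm: float = 421.0
    ligand_M: Optional[float] = None
    enzyme_M: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.t.shape != self.A.shape:
            raise ValueError("t and A must have the same shape")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("absorbance contains non-finite values")

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "A": self.A})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "ProgressCurve":
        return cls(df["t_s"].to_numpy(), df["A"].to_numpy(), **kw)


@dataclass
class Phase:
    amplitude: float  # signed, AU
    k_obs: float      # s^-1
    amplitude_se: float
    k_obs_se: float

    @property
    def sign_class(self) -> str:
        return "hyperchromic" if self.amplitude < 0 else "hypochromic"


@dataclass
class ExpFit:
    """Multi-exponential fit result; phases sorted by descending k_obs."""

    phases: list[Phase]
    offset: float          # plateau A_inf
    offset_se: float
    ssr: float
    aicc: float
    n_points: int
    degenerate_rates: bool = False

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def amplitude_negligible(self, n_se: float = 2.0) -> bool:
        """True if any phase amplitude is within ``n_se`` SEs of zero."""
        return any(abs(p.amplitude) < n_se * p.amplitude_se for p in self.phases)

    def rate_indeterminate(self, n_se: float = 2.0) -> bool:
        """True if any phase rate is within ``n_se`` SEs of zero, i.e. the
        data do not pin the rate down at all."""
        return any(p.k_obs < n_se * p.k_obs_se for p in self.phases)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset, dtype=float)
        for p in self.phases:
            out += p.amplitude * np.exp(-p.k_obs * t)
        return out


class ExponentialRelaxation(BaseEstimator, RegressorMixin):
    """Fit ``n_phases`` exponentials plus a plateau to a progress curve.

    ``X`` is the time vector (s), ``y`` the absorbance.  Variable-projection
    NLS with multistart over log-spaced rate seeds spanning the observable
    window [1/t_max, n_points/(2·t_max)] (rates much faster than the sampling
    or slower than the record are not recoverable).

    Attributes: ``fit_`` (:class:`ExpFit`), ``rates_``, ``amplitudes_``,
    ``offset_``.
    """

    def __init__(self, n_phases: int = 1, n_starts: int = 12, random_state: int = 0):
        self.n_phases = n_phases
        self.n_starts = n_starts
        self.random_state = random_state

    @staticmethod
    def _design(t: np.ndarray, rates: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones_like(t)] + [np.exp(-k * t) for k in rates])

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        A = np.asarray(y, dtype=float).reshape(-1)
        n = int(self.n_phases)
        if n < 1:
            raise ValueError("n_phases must be >= 1")
        if t.size < 5 * (2 * n + 1):
            raise ValueError(
                f"need at least {5 * (2 * n + 1)} points for {n} phases, got {t.size}"
            )
        t0 = t - t[0]  # fit relative to the first sample
        t_span = float(t0[-1])
        # rates outside [0.2/record length, 2x sampling rate] are not
        # resolvable from the trace and are excluded by the fit bounds
        k_lo = np.log(0.2 / t_span)
        k_hi = np.log(2.0 * t.size / t_span)

        def solve_linear(log_k):
            M = self._design(t0, np.exp(log_k))
            coef, *_ = np.linalg.lstsq(M, A, rcond=None)
            return coef, M

        def residual(log_k):
            coef, M = solve_linear(log_k)
            return M @ coef - A

        rng = np.random.default_rng(self.random_state)
        seeds = [np.sort(np.linspace(k_lo, k_hi, n + 2)[1:-1][::-1])]
        # log-spaced deterministic ladders at several offsets, then random
        for frac in (0.25, 0.5, 0.75):
            base = k_lo + frac * (k_hi - k_lo)
            seeds.append(np.sort(base + np.arange(n) * np.log(10.0))[::-1])
        while len(seeds) < self.n_starts:
            seeds.append(np.sort(rng.uniform(k_lo, k_hi, size=n))[::-1])

        best = None
        seeds = [np.clip(s, k_lo + 1e-9, k_hi - 1e-9) for s in seeds]
        for x0 in seeds[: self.n_starts]:
            try:
                res = least_squares(residual, x0, method="trf",
                                    bounds=(k_lo, k_hi),
                                    xtol=1e-14, ftol=1e-14)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise FitFailure("exponential fit did not converge from any start")

        rates = np.exp(best.x)
        coef, _ = solve_linear(best.x)
        order = np.argsort(rates)[::-1]
        rates = rates[order]
        amps = coef[1:][order]
        offset = float(coef[0])

        # covariance of the full parametrisation (offset, amps, rates)
        ssr = float(2 * best.cost)
        J = np.empty((t.size, 1 + 2 * len(rates)))
        J[:, 0] = 1.0
        for i, (a, k) in enumerate(zip(amps, rates)):
            e = np.exp(-k * t0)
            J[:, 1 + i] = e
            J[:, 1 + len(rates) + i] = -a * t0 * e
        cov = covariance_from_jacobian(J, ssr, t.size)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))

        degenerate = bool(
            len(rates) > 1 and np.any(rates[:-1] / rates[1:] < RATE_DEGENERACY_RATIO)
        )
        if len(rates) > 1 and np.any(np.abs(np.diff(rates)) < 1e-9):
            degenerate = True

        phases = [
            Phase(float(a), float(k), float(se[1 + i]), float(se[1 + len(rates) + i]))
            for i, (a, k) in enumerate(zip(amps, rates))
        ]
        self.fit_ = ExpFit(
            phases=phases, offset=offset, offset_se=float(se[0]), ssr=ssr,
            aicc=aicc(ssr, t.size, 1 + 2 * n), n_points=t.size,
            degenerate_rates=degenerate,
        )
        self.rates_ = rates
        self.amplitudes_ = amps
        self.offset_ = offset
        self._t0_ = float(t[0])
        return self

    def predict(self, X):
        check_is_fitted(self, "fit_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.fit_.predict(t - self._t0_)


def fit_exponentials(curve: ProgressCurve, n: int, n_starts: int = 12,
                     random_state: int = 0) -> ExpFit:
    """Fit ``n`` exponential phases to a progress curve; see
    :class:`ExponentialRelaxation`."""
    est = ExponentialRelaxation(n_phases=n, n_starts=n_starts,
                                random_state=random_state)
    est.fit(curve.t, curve.A)
    return est.fit_


@dataclass
class PhaseSelection:
    selected_n: int
    fits: dict[int, ExpFit]
    aicc: dict[int, float]
    excluded: dict[int, str]
    amplitude_flag: bool = False  # selected fit has a near-zero amplitude


def select_n_phases(curve: ProgressCurve, max_n: int = 3,
                    random_state: int = 0) -> PhaseSelection:
    """Choose the number of exponential phases by AICc.

    Fits n = 1..max_n; candidates whose fit is ill-conditioned — degenerate
    rates, an amplitude indistinguishable from zero (|a| < 2·SE), or a rate
    indistinguishable from zero — are excluded from the comparison.  If every candidate is excluded the
    single-exponential fit is returned with ``amplitude_flag`` set (the
    pure-noise case).
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    fits: dict[int, ExpFit] = {}
    excluded: dict[int, str] = {}
    for n in range(1, max_n + 1):
        try:
            fits[n] = fit_exponentials(curve, n, random_state=random_state)
        except (ValueError, FitFailure) as exc:
            excluded[n] = str(exc)
            continue
        if fits[n].degenerate_rates:
            excluded[n] = "degenerate rates"
        elif fits[n].amplitude_negligible():
            excluded[n] = "amplitude within 2 SE of zero"
        elif fits[n].rate_indeterminate():
            excluded[n] = "rate within 2 SE of zero"

    candidates = {n: f.aicc for n, f in fits.items() if n not in excluded}
    if not candidates:
        n_sel = min(fits) if fits else 1
        if n_sel not in fits:
            raise FitFailure("no phase count could be fitted")
        return PhaseSelection(n_sel, fits, {n: f.aicc for n, f in fits.items()},
                              excluded, amplitude_flag=True)
    n_sel = min(candidates, key=candidates.get)
    flag = fits[n_sel].amplitude_negligible()
    return PhaseSelection(n_sel, fits, {n: f.aicc for n, f in fits.items()},
                          excluded, amplitude_flag=flag)


def classify_phases(fit: ExpFit) -> list[str]:
    """Sign classes of the phases in temporal order (descending k_obs).

    A negative amplitude relaxes upward (hyperchromic), positive downward
    (hypochromic).
    """
    return [p.sign_class for p in fit.phases]


def collect_kobs(fits: Sequence[tuple[float, ExpFit]],
                 phase_labels: Sequence[str] = ("fast", "slow", "third"),
                 ) -> dict[str, KobsSeries]:
    """Assemble per-phase k_obs series from fits at several concentrations.

    ``fits`` is a sequence of (ligand concentration M, ExpFit).  Phases are
    matched across concentrations by rank of k_obs (fastest first).  Curves
    whose phase count differs from the majority are excluded from the extra
    phases with a warning, so a partial table is still produced.
    """
    if not fits:
        raise ValueError("no fits supplied")
    counts = np.array([f.n_phases for _, f in fits])
    n_common = int(np.bincount(counts).argmax())
    if np.any(counts != n_common):
        bad = [x for (x, f), c in zip(fits, counts) if c != n_common]
        warnings.warn(
            f"phase-count mismatch at concentrations {bad}: only the first "
            f"{n_common} phases (by rate rank) enter the table"
        )
    series: dict[str, KobsSeries] = {}
    for rank in range(n_common):
        rows = [
            (x, f.phases[rank].k_obs, f.phases[rank].k_obs_se)
            for x, f in fits
            if f.n_phases > rank
        ]
        rows.sort(key=lambda r: r[0])
        x, k, se = map(np.array, zip(*rows))
        label = phase_labels[rank] if rank < len(phase_labels) else f"phase{rank + 1}"
        series[label] = KobsSeries(x, k, se=se, phase=label)
    return series
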