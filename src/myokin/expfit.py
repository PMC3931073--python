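"""Single/double exponential fitting of stopped-flow transients.

The model is

    y(t) = y_inf + sum_j b_j * exp(-k_j * t),    j = 1..n_phases

fitted by unweighted least squares (instrument noise is approximately
homoscedastic).  Rates are optimised on a log scale with the linear
coefficients obtained by projection at every step (variable projection),
which makes the fit fast and insensitive to amplitude starting values.
Phase amplitudes are reported in the stopped-flow convention: percent of
the pre-mix fluorescence level, signed so a rise is positive
(``amplitude_j = -b_j * 100 / premix``).

Phase-count selection uses the extra-sum-of-squares F-test at
``alpha = 0.01`` with ties resolved in favour of fewer phases.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import scipy.optimize
import scipy.stats
from sklearn.base import BaseEstimator

from .trace import FluorescenceTrace

__all__ = [
    "Phase",
    "ExpFitResult",
    "ExponentialTransientFitter",
    "fit_exponentials",
    "select_phase_count",
    "FitConvergenceWarning",
]


class FitConvergenceWarning(UserWarning):
    """Emitted when an exponential fit fails to converge after restarts."""


@dataclass(frozen=True)
class Phase:
    """One exponential phase: amplitude (% of pre-mix level) and rate."""

    amplitude_pct: float
    kobs: float
    se_amplitude_pct: float = float("nan")
    se_kobs: float = float("nan")


@dataclass
class ExpFitResult:
    """Fitted exponential phases, sorted fast to slow.

    ``baseline`` is the end level y_inf on the relative-fluorescence
    scale; ``rss`` the residual sum of squares; ``converged`` is False
    only when every restart failed (the best attempt is still reported).
    """

    phases: list[Phase]
    baseline: float
    rss: float
    n_phases: int
    converged: bool
    se_baseline: float = float("nan")
    f_pvalue: Optional[float] = None

    @property
    def rates(self) -> np.ndarray:
        return np.array([p.kobs for p in self.phases])

    @property
    def amplitudes_pct(self) -> np.ndarray:
        return np.array([p.amplitude_pct for p in self.phases])

    @property
    def dominant_phase(self) -> Phase:
        """Phase with the largest absolute amplitude (what an
        experimentalist labels the principal phase of the record)."""
        return max(self.phases, key=lambda p: abs(p.amplitude_pct))

    def predict(self, t: np.ndarray, premix_level: float = 1.0) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.baseline)
        for p in self.phases:
            b = -p.amplitude_pct / 100.0 * premix_level
            y = y + b * np.exp(-p.kobs * t)
        return y

    def to_dict(self) -> dict:
        return {
            "n_phases": self.n_phases,
            "baseline": self.baseline,
            "se_baseline": self.se_baseline,
            "rss": self.rss,
            "converged": self.converged,
            "f_pvalue": self.f_pvalue,
            "phases": [
                {"amplitude_pct": p.amplitude_pct, "kobs": p.kobs,
                 "se_amplitude_pct": p.se_amplitude_pct, "se_kobs": p.se_kobs}
                for p in self.phases
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=float, **kwargs)


def _design(t: np.ndarray, rates: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(t)] + [np.exp(-k * t) for k in rates])


def _project(t: np.ndarray, y: np.ndarray, rates: np.ndarray):
    X = _design(t, rates)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef, y - X @ coef


def _initial_rates(t: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """Reproducible starting rates: fast = 3 / t10 where t10 is the time
    to 10% of the total observed change; slow = fast / 20."""
    total = y[-1] - y[0]
    if total == 0:
        k_fast = 1.0 / (t[-1] - t[0])
    else:
        frac = np.abs((y - y[0]) / total)
        above = np.nonzero(frac >= 0.1)[0]
        t10 = t[above[0]] if above.size else t[len(t) // 10]
        k_fast = 3.0 / max(t10, 1e-9)
    if n == 1:
        return np.array([k_fast])
    return np.array([k_fast, k_fast / 20.0])


def _fit_n_phases(t: np.ndarray, y: np.ndarray, n: int,
                  n_restarts: int) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Variable-projection fit of n exponentials.

    Returns (rates, coefficients [y_inf, b_1..b_n], rss, converged).
    """

    # rates outside [1e-6, 1e8] s^-1 are physically meaningless on any
    # stopped-flow time base; clamping also keeps exp() finite
    def residual(logk: np.ndarray) -> np.ndarray:
        _, r = _project(t, y, np.exp(np.clip(logk, -13.8, 18.4)))
        return r

    base = np.log(_initial_rates(t, y, n))
    # multi-start: log-spaced perturbations of the heuristic guess
    factors = [1.0, 0.3, 3.0, 0.1, 10.0][:max(1, n_restarts)]
    best = None
    converged = False
    for f in factors:
        x0 = base + np.log(f)
        try:
            sol = scipy.optimize.least_squares(residual, x0, method="lm",
                                               xtol=1e-14, ftol=1e-14,
                                               max_nfev=4000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        distinct = (n == 1 or
                    np.abs(np.diff(np.sort(sol.x)))[0] > 1e-6)
        if best is None or rss < best[0]:
            best = (rss, sol.x)
        if sol.status > 0 and distinct:
            converged = converged or True
    if best is None:  # all restarts raised
        rates = np.exp(base)
        coef, r = _project(t, y, rates)
        return rates, coef, float(np.sum(r ** 2)), False
    rss, logk = best
    rates = np.exp(np.clip(logk, -13.8, 18.4))
    order = np.argsort(-rates)
    rates = rates[order]
    coef, _ = _project(t, y, rates)
    # reorder b coefficients to match sorted rates (column 0 is intercept)
    return rates, coef, rss, converged


def _standard_errors(t: np.ndarray, y: np.ndarray, rates: np.ndarray,
                     coef: np.ndarray, rss: float):
    """Local quadratic (Gauss-Newton) covariance of (y_inf, b_j, k_j)."""
    n = len(rates)
    N = len(t)
    p = 2 * n + 1
    cols = [np.ones_like(t)]
    cols += [np.exp(-k * t) for k in rates]
    cols += [-coef[1 + j] * t * np.exp(-rates[j] * t) for j in range(n)]
    J = np.column_stack(cols)
    dof = max(N - p, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return se  # [se_yinf, se_b..., se_k...]


class ExponentialTransientFitter(BaseEstimator):
    """Least-squares single/double exponential fitter (sklearn style).

    Parameters
    ----------
    n_phases : {"auto", 1, 2}
        Number of exponential phases; ``"auto"`` selects between 1 and 2
        by the extra-sum-of-squares F-test.
    alpha : float
        Significance level of the F-test used by ``"auto"``.
    n_restarts : int
        Multi-start perturbations tried before declaring non-convergence.
    premix_level : float or None
        Pre-mix fluorescence level used to express amplitudes in percent;
        ``None`` takes it from the trace metadata (default 1.0).

    Attributes
    ----------
    rates_ : ndarray, fitted kobs values sorted fast to slow (s⁻¹)
    amplitudes_pct_ : ndarray, signed amplitudes (% of pre-mix level)
    baseline_ : float, end level
    rss_ : float, residual sum of squares
    n_phases_ : int, phases actually fitted
    converged_ : bool
    result_ : :class:`ExpFitResult`
    """

    def __init__(self, n_phases: Union[str, int] = "auto", alpha: float = 0.01,
                 n_restarts: int = 5, premix_level: Optional[float] = None):
        self.n_phases = n_phases
        self.alpha = alpha
        self.n_restarts = n_restarts
        self.premix_level = premix_level

    # -- internal ------------------------------------------------------
    def _fit_result(self, t, y, n, premix) -> ExpFitResult:
        rates, coef, rss, converged = _fit_n_phases(t, y, n, self.n_restarts)
        if not converged:
            warnings.warn(
                f"{n}-phase exponential fit did not converge after "
                f"{self.n_restarts} restarts; reporting best attempt",
                FitConvergenceWarning, stacklevel=3)
        se = _standard_errors(t, y, rates, coef, rss)
        phases = []
        for j in range(n):
            phases.append(Phase(
                amplitude_pct=float(-coef[1 + j] / premix * 100.0),
                kobs=float(rates[j]),
                se_amplitude_pct=float(se[1 + j] / premix * 100.0),
                se_kobs=float(se[1 + n + j]),
            ))
        return ExpFitResult(phases=phases, baseline=float(coef[0]),
                            rss=rss, n_phases=n, converged=converged,
                            se_baseline=float(se[0]))

    def fit(self, t, y=None):
        """Fit the transient.

        Accepts either ``fit(trace)`` with a :class:`FluorescenceTrace`
        or ``fit(t, y)`` with plain arrays.
        """
        if isinstance(t, FluorescenceTrace):
            trace, y = t, t.signal
            tt = trace.time
            premix = self.premix_level or trace.premix_level
        else:
            tt = np.asarray(t, dtype=float).ravel()
            y = np.asarray(y, dtype=float).ravel()
            premix = self.premix_level or 1.0
        if tt.size != y.size or tt.size < 10:
            raise ValueError("need matching time/signal arrays (>= 10 points)")

        if self.n_phases in (1, 2):
            res = self._fit_result(tt, y, int(self.n_phases), premix)
        elif self.n_phases == "auto":
            res = self._select(tt, y, premix)
        else:
            raise ValueError("n_phases must be 1, 2 or 'auto'")

        self.result_ = res
        self.rates_ = res.rates
        self.amplitudes_pct_ = res.amplitudes_pct
        self.baseline_ = res.baseline
        self.rss_ = res.rss
        self.n_phases_ = res.n_phases
        self.converged_ = res.converged
        return self

    def _select(self, t, y, premix) -> ExpFitResult:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", FitConvergenceWarning)
            fit1 = self._fit_result(t, y, 1, premix)
            fit2 = self._fit_result(t, y, 2, premix)
        for w in caught:  # re-emit anything unrelated to selection
            if not issubclass(w.category, FitConvergenceWarning):
                warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
        if not fit2.converged and fit1.converged:
            warnings.warn("2-phase fit non-convergent; selecting 1 phase",
                          FitConvergenceWarning, stacklevel=2)
            return fit1
        if not fit1.converged and fit2.converged:
            warnings.warn("1-phase fit non-convergent; selecting 2 phases",
                          FitConvergenceWarning, stacklevel=2)
            return fit2
        N = len(t)
        scale = max(np.ptp(y), abs(np.mean(y)), 1e-300)
        tol = (1e-7 * scale) ** 2 * N
        if fit1.rss <= tol:  # single exponential already at machine level
            fit1.f_pvalue = 1.0
            return fit1
        if fit2.rss <= 0 or fit2.rss >= fit1.rss:
            p = 0.0 if fit2.rss < fit1.rss else 1.0
        else:
            F = ((fit1.rss - fit2.rss) / 2.0) / (fit2.rss / max(N - 5, 1))
            p = float(scipy.stats.f.sf(F, 2, max(N - 5, 1)))
        if p < self.alpha and _phases_distinct(fit2):
            fit2.f_pvalue = p
            return fit2
        fit1.f_pvalue = p
        return fit1

    def predict(self, t) -> np.ndarray:
        if not hasattr(self, "result_"):
            raise RuntimeError("fitter is not fitted")
        premix = self.premix_level or 1.0
        return self.result_.predict(np.asarray(t, dtype=float), premix)


def _phases_distinct(res: ExpFitResult, min_ratio: float = 1.001) -> bool:
    k = np.sort(res.rates)
    if k[0] <= 0:
        return False
    return bool(k[-1] / k[0] > min_ratio and
                np.all(np.abs(res.amplitudes_pct) > 1e-9))


def fit_exponentials(trace: FluorescenceTrace,
                     n_phases: Union[int, str] = 2) -> ExpFitResult:
    """Fit ``n_phases`` exponentials to a trace and return the result."""
    return ExponentialTransientFitter(n_phases=n_phases).fit(trace).result_


def select_phase_count(trace: FluorescenceTrace, alpha: float = 0.01) -> int:
    """Choose 1 vs 2 phases by the extra-sum-of-squares F-test."""
    fitter = ExponentialTransientFitter(n_phases="auto", alpha=alpha).fit(trace)
    return fitter.n_phases_
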