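"""Secondary analyses of fitted phase parameters.

Everything downstream of the per-trace exponential fits lives here:

* hyperbolic dependence of the fast-phase kobs on [ATP]
  (``kobs = k_max [ATP] / ([ATP] + K_half)``), whose plateau and
  half-saturation are read as the isomerisation rate and 1/K1;
* the low-concentration linear regime giving the apparent second-order
  binding constant;
* competitive inhibition of ATP-induced dissociation by ADP
  (``kobs = kobs(0) / (1 + [ADP]/K_AD)``);
* the fast/slow amplitude-ratio route to the rigor conformer
  equilibrium (``K_alpha = A_fast / A_slow``);
* the tight-binding quadratic titration isotherm for actin affinity;
* the binding- vs hydrolysis-limited phase-assignment diagnostic;
* derived constants (1/K1, detached lifetime, affinity ratios) and the
  two-construct comparison with Welch tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "KobsSeries",
    "TitrationCurve",
    "DerivedConstants",
    "HyperbolaFitter",
    "LinearLowConcFitter",
    "AdpCompetitionFitter",
    "QuadraticTitrationFitter",
    "fit_hyperbola",
    "fit_linear_low_conc",
    "fit_adp_competition",
    "fit_quadratic_titration",
    "k_minus_alpha_from_amplitudes",
    "overall_KAD",
    "implied_site_KADP",
    "assign_fast_phase",
    "PhaseAssignment",
    "derive_constants",
    "compare_constructs",
    "detection_power",
    "SaturationError",
    "ModelViolationError",
    "TightBindingWarning",
]

MIN_NONLINEAR_POINTS = 5


class SaturationError(ValueError):
    """Concentration range shows no curvature; plateau not constrained."""


class ModelViolationError(ValueError):
    """Data contradict the assumed model form."""


class TightBindingWarning(UserWarning):
    """Affinity far below the fixed-partner concentration: upper bound only."""


# ---------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------

@dataclass
class KobsSeries:
    """Observed rate (and amplitude) versus ligand concentration."""

    ligand: str                      # "ATP" | "ADP" | "S1"
    conc_um: np.ndarray
    kobs: np.ndarray
    amplitude_pct: Optional[np.ndarray] = None
    phase: str = "fast"

    def __post_init__(self) -> None:
        self.conc_um = np.asarray(self.conc_um, dtype=float)
        self.kobs = np.asarray(self.kobs, dtype=float)
        if self.conc_um.shape != self.kobs.shape:
            raise ValueError("concentration and kobs grids differ in length")
        if np.any(np.diff(self.conc_um) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.amplitude_pct is not None:
            self.amplitude_pct = np.asarray(self.amplitude_pct, dtype=float)

    def __len__(self) -> int:
        return self.conc_um.size


@dataclass
class TitrationCurve:
    """Transient amplitude versus total S1 at fixed actin concentration."""

    s1_tot_nm: np.ndarray
    amplitude_pct: np.ndarray
    a0_nm: float
    with_adp: bool = False

    def __post_init__(self) -> None:
        self.s1_tot_nm = np.asarray(self.s1_tot_nm, dtype=float)
        self.amplitude_pct = np.asarray(self.amplitude_pct, dtype=float)
        if self.s1_tot_nm.shape != self.amplitude_pct.shape:
            raise ValueError("grids differ in length")
        if np.any(self.amplitude_pct < -1e-9):
            raise ValueError("amplitudes must be >= 0")
        if self.a0_nm <= 0:
            raise ValueError("actin concentration must be > 0")
        if not (self.s1_tot_nm.min() < self.a0_nm < self.s1_tot_nm.max()):
            raise ValueError(
                "titration grid must bracket the actin concentration")


# ---------------------------------------------------------------------
# Hyperbolic ATP dependence
# ---------------------------------------------------------------------

def _nls_cov(jac: np.ndarray, rss: float, n: int, p: int) -> np.ndarray:
    dof = max(n - p, 1)
    return rss / dof * np.linalg.pinv(jac.T @ jac)


class HyperbolaFitter(BaseEstimator, RegressorMixin):
    """Fit ``kobs = k_max c / (c + K_half)`` to a fast-phase series.

    Attributes
    ----------
    k_max_ : float, plateau rate (s⁻¹)
    k_half_ : float, half-saturating concentration (μM)
    initial_slope_ : float, ``k_max_/k_half_`` (μM⁻¹s⁻¹, derived)
    se_k_max_, se_k_half_, se_initial_slope_ : standard errors
    """

    #: fitted K_half may not exceed max(conc)/this factor
    saturation_factor = 0.3

    def fit(self, conc, kobs):
        c = np.asarray(conc, dtype=float).ravel()
        k = np.asarray(kobs, dtype=float).ravel()
        if c.size != k.size:
            raise ValueError("conc and kobs differ in length")
        if c.size < MIN_NONLINEAR_POINTS:
            raise ValueError(
                f">= {MIN_NONLINEAR_POINTS} concentrations required")
        if np.ptp(k) <= 1e-12 * max(1.0, np.abs(k).max()):
            raise SaturationError("kobs series is constant; no curvature")

        kmax0 = 1.05 * k.max()
        half = 0.5 * k.max()
        above = np.nonzero(k >= half)[0]
        khalf0 = c[above[0]] if above.size else np.median(c)
        khalf0 = max(khalf0, 1e-6)

        def resid(x):
            km, kh = np.exp(x)
            return km * c / (c + kh) - k

        sol = scipy.optimize.least_squares(
            resid, np.log([kmax0, khalf0]), method="lm",
            xtol=1e-14, ftol=1e-14, max_nfev=2000)
        km, kh = np.exp(sol.x)
        if kh > c.max() / self.saturation_factor:
            raise SaturationError(
                f"saturation not reached: fitted K_half = {kh:.3g} μM vs "
                f"max concentration {c.max():.3g} μM")
        rss = float(np.sum(sol.fun ** 2))
        J = np.column_stack([c / (c + kh), -km * c / (c + kh) ** 2])
        cov = _nls_cov(J, rss, c.size, 2)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        slope = km / kh
        # delta method for the derived slope
        g = np.array([1.0 / kh, -km / kh ** 2])
        se_slope = float(np.sqrt(max(g @ cov @ g, 0.0)))

        self.k_max_, self.k_half_ = float(km), float(kh)
        self.initial_slope_ = float(slope)
        self.se_k_max_, self.se_k_half_ = float(se[0]), float(se[1])
        self.se_initial_slope_ = se_slope
        self.rss_ = rss
        return self

    def predict(self, conc):
        c = np.asarray(conc, dtype=float)
        return self.k_max_ * c / (c + self.k_half_)


@dataclass(frozen=True)
class HyperbolaFit:
    k_max: float
    k_half: float
    initial_slope: float
    se_k_max: float
    se_k_half: float
    se_initial_slope: float
    rss: float


def fit_hyperbola(series: KobsSeries) -> HyperbolaFit:
    """Hyperbolic saturation fit of a fast-phase kobs series."""
    if series.phase != "fast":
        raise ValueError("hyperbola fit expects the fast-phase series")
    est = HyperbolaFitter().fit(series.conc_um, series.kobs)
    return HyperbolaFit(est.k_max_, est.k_half_, est.initial_slope_,
                        est.se_k_max_, est.se_k_half_,
                        est.se_initial_slope_, est.rss_)


class LinearLowConcFitter(BaseEstimator, RegressorMixin):
    """Second-order binding constant from the linear low-[ATP] regime.

    Fits ``kobs = slope * c`` (through the origin by default).
    """

    def __init__(self, through_origin: bool = True):
        self.through_origin = through_origin

    def fit(self, conc, kobs):
        c = np.asarray(conc, dtype=float).ravel()
        k = np.asarray(kobs, dtype=float).ravel()
        if c.size < 3:
            raise ValueError(">= 3 points required in the linear regime")
        if self.through_origin:
            sxx = float(c @ c)
            slope = float(c @ k) / sxx
            resid = k - slope * c
            dof = max(c.size - 1, 1)
            se = math.sqrt(float(resid @ resid) / dof / sxx)
            intercept = 0.0
        else:
            A = np.column_stack([c, np.ones_like(c)])
            coef, rss_arr, *_ = np.linalg.lstsq(A, k, rcond=None)
            slope, intercept = float(coef[0]), float(coef[1])
            resid = k - A @ coef
            dof = max(c.size - 2, 1)
            cov = float(resid @ resid) / dof * np.linalg.pinv(A.T @ A)
            se = math.sqrt(max(cov[0, 0], 0.0))
        self.slope_ = slope
        self.intercept_ = intercept
        self.se_slope_ = se
        return self

    def predict(self, conc):
        return self.slope_ * np.asarray(conc, dtype=float) + self.intercept_


def fit_linear_low_conc(series: KobsSeries, k_half: Optional[float] = None,
                        through_origin: bool = True) -> tuple[float, float]:
    """Slope ± SE (μM⁻¹s⁻¹) of kobs vs concentration at low saturation.

    With ``k_half`` given, only points at ``c <= 0.2 * k_half`` enter the
    fit; at least 3 such points are required.
    """
    c, k = series.conc_um, series.kobs
    if k_half is not None:
        mask = c <= 0.2 * k_half
        c, k = c[mask], k[mask]
    if c.size < 3:
        raise ValueError(
            f"only {c.size} points in the linear regime (need >= 3)")
    est = LinearLowConcFitter(through_origin=through_origin).fit(c, k)
    return est.slope_, est.se_slope_


# ---------------------------------------------------------------------
# ADP competition
# ---------------------------------------------------------------------

class AdpCompetitionFitter(BaseEstimator, RegressorMixin):
    """Fit ``kobs = k0 / (1 + [ADP]/K_AD)`` to a dilution series.

    ``k0`` (the uninhibited rate) is estimated jointly with the affinity
    rather than fixed at the zero-ADP observation, which reduces bias
    from a single noisy operating point.
    """

    def fit(self, adp_um, kobs):
        d = np.asarray(adp_um, dtype=float).ravel()
        k = np.asarray(kobs, dtype=float).ravel()
        if d.size < MIN_NONLINEAR_POINTS:
            raise ValueError(
                f">= {MIN_NONLINEAR_POINTS} ADP concentrations required")
        if np.ptp(d) <= 0:
            raise ValueError("need a range of ADP concentrations "
                             "(no inhibition information)")
        slope = scipy.stats.linregress(d, k).slope
        if slope > 0 and k[-1] > k[0]:
            raise ModelViolationError(
                "kobs increases with [ADP]; competitive-inhibition model "
                "violated")
        k0_0 = max(k.max(), 1e-9)
        kad0 = max(np.median(d[d > 0]) if np.any(d > 0) else 1.0, 1e-6)

        def resid(x):
            k0, kad = np.exp(x)
            return k0 / (1.0 + d / kad) - k

        sol = scipy.optimize.least_squares(
            resid, np.log([k0_0, kad0]), method="lm",
            xtol=1e-14, ftol=1e-14, max_nfev=2000)
        k0, kad = np.exp(sol.x)
        rss = float(np.sum(sol.fun ** 2))
        denom = 1.0 + d / kad
        J = np.column_stack([1.0 / denom, k0 * d / (kad * denom) ** 2])
        cov = _nls_cov(J, rss, d.size, 2)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        self.k0_, self.K_AD_ = float(k0), float(kad)
        self.se_k0_, self.se_K_AD_ = float(se[0]), float(se[1])
        self.rss_ = rss
        return self

    def predict(self, adp_um):
        return self.k0_ / (1.0 + np.asarray(adp_um, dtype=float) / self.K_AD_)


@dataclass(frozen=True)
class AdpCompetitionFit:
    K_AD: float
    se_K_AD: float
    k0: float
    se_k0: float
    predicted_k0: Optional[float] = None


def fit_adp_competition(series: KobsSeries, atp_conc_um: Optional[float] = None,
                        K1k2_prime: Optional[float] = None) -> AdpCompetitionFit:
    """Apparent ADP affinity of acto·S1 from competition with ATP.

    ``atp_conc_um`` and ``K1k2_prime`` are optional and only used to
    report the model-predicted uninhibited rate
    ``K1k2_prime * [ATP]`` alongside the jointly fitted one.
    """
    if series.ligand.upper() != "ADP":
        raise ValueError("competition fit expects an ADP series")
    est = AdpCompetitionFitter().fit(series.conc_um, series.kobs)
    pred = (K1k2_prime * atp_conc_um
            if (atp_conc_um is not None and K1k2_prime is not None) else None)
    return AdpCompetitionFit(est.K_AD_, est.se_K_AD_, est.k0_, est.se_k0_, pred)


# ---------------------------------------------------------------------
# Amplitude-ratio equilibrium constants
# ---------------------------------------------------------------------

def k_minus_alpha_from_amplitudes(a_fast_pct: float, a_slow_pct: float,
                                  k_plus_alpha: float) -> tuple[float, float]:
    """Conformer equilibrium and reverse rate from phase amplitudes.

    ``K_alpha = A_fast / A_slow`` and ``k_minus_alpha = k_plus_alpha /
    K_alpha``.  A vanishing slow amplitude returns the fast-myosin
    sentinel ``(inf, 0.0)`` (only a single phase observable).
    """
    if a_fast_pct < 0 or a_slow_pct < 0:
        raise ValueError("amplitudes must be >= 0")
    if k_plus_alpha <= 0:
        raise ValueError("k_plus_alpha must be > 0")
    if a_slow_pct == 0:
        return math.inf, 0.0
    K_alpha = a_fast_pct / a_slow_pct
    return K_alpha, k_plus_alpha / K_alpha


def overall_KAD(K_ADP: float, K_alphaD: float,
                convention: str = "partition") -> float:
    """Overall ADP dissociation constant of the actin·S1 complex.

    Combines the A·M site constant ``K_ADP`` with the bound-state
    conformer equilibrium ``K_alphaD = [A·M·D]/[A·M′·D]``.

    ``convention="partition"`` (default): partitioning of the bound state
    into the extra A·M′·D conformer increases total binding, tightening
    the overall affinity::

        K_AD = K_ADP / (1 + 1/K_alphaD)

    ``convention="reciprocal"``: the reciprocal-ratio form, which weakens
    the overall affinity instead::

        K_AD = K_ADP * (1 + 1/K_alphaD)

    Both reduce to ``K_ADP`` as the isomer disappears (K_alphaD → inf).
    """
    if K_ADP <= 0 or K_alphaD <= 0:
        raise ValueError("equilibrium constants must be > 0")
    factor = 1.0 + 1.0 / K_alphaD
    if convention == "partition":
        return K_ADP / factor
    if convention == "reciprocal":
        return K_ADP * factor
    raise ValueError("convention must be 'partition' or 'reciprocal'")


def implied_site_KADP(K_AD: float, K_alphaD: float,
                      convention: str = "partition") -> float:
    """Inverse of :func:`overall_KAD`: the site constant implied by an
    observed overall affinity."""
    if K_AD <= 0 or K_alphaD <= 0:
        raise ValueError("equilibrium constants must be > 0")
    factor = 1.0 + 1.0 / K_alphaD
    if convention == "partition":
        return K_AD * factor
    if convention == "reciprocal":
        return K_AD / factor
    raise ValueError("convention must be 'partition' or 'reciprocal'")


# ---------------------------------------------------------------------
# Quadratic tight-binding titration
# ---------------------------------------------------------------------

def bound_fraction_quadratic(m_tot: np.ndarray, a0: float,
                             kd: float) -> np.ndarray:
    """Fraction of actin with S1 bound, from the tight-binding quadratic.

    The physically significant root of
    ``a0*x^2 - (a0 + m + kd)*x + m = 0`` — the one lying in
    ``[0, min(a0, m)/a0]`` — is the smaller root.
    """
    m = np.asarray(m_tot, dtype=float)
    b = a0 + m + kd
    disc = np.sqrt(np.clip(b * b - 4.0 * a0 * m, 0.0, None))
    return (b - disc) / (2.0 * a0)


class QuadraticTitrationFitter(BaseEstimator, RegressorMixin):
    """Fit the tight-binding isotherm to amplitude vs total S1.

    Model: ``amplitude = scale * alpha(M; K_D, A0)`` where ``alpha`` is
    the bound fraction from the quadratic.  Emits
    :class:`TightBindingWarning` when the fitted ``K_D`` falls below
    ``A0/50`` (only an upper bound is then meaningful).
    """

    def __init__(self, a0_nm: float = 30.0):
        self.a0_nm = a0_nm

    def fit(self, s1_tot_nm, amplitude):
        m = np.asarray(s1_tot_nm, dtype=float).ravel()
        a = np.asarray(amplitude, dtype=float).ravel()
        if m.size < MIN_NONLINEAR_POINTS:
            raise ValueError(
                f">= {MIN_NONLINEAR_POINTS} titration points required")
        a0 = float(self.a0_nm)
        scale0 = max(a.max(), 1e-9)
        kd0 = max(a0, 1e-3)

        def resid(x):
            scale, kd = np.exp(x)
            return scale * bound_fraction_quadratic(m, a0, kd) - a

        sol = scipy.optimize.least_squares(
            resid, np.log([scale0, kd0]), method="lm",
            xtol=1e-15, ftol=1e-15, max_nfev=4000)
        scale, kd = np.exp(sol.x)
        rss = float(np.sum(sol.fun ** 2))
        # numeric jacobian in (scale, kd) for the covariance
        eps = 1e-6
        f0 = scale * bound_fraction_quadratic(m, a0, kd)
        d_scale = bound_fraction_quadratic(m, a0, kd)
        d_kd = (scale * bound_fraction_quadratic(m, a0, kd * (1 + eps)) - f0) \
            / (kd * eps)
        J = np.column_stack([d_scale, d_kd])
        cov = _nls_cov(J, rss, m.size, 2)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        self.scale_, self.K_D_ = float(scale), float(kd)
        self.se_scale_, self.se_K_D_ = float(se[0]), float(se[1])
        self.rss_ = rss
        self.tight_binding_ = bool(kd < a0 / 50.0)
        if self.tight_binding_:
            warnings.warn(
                f"tight-binding limit: K_D = {kd:.3g} nM < A0/50 = "
                f"{a0 / 50:.3g} nM; treat as an upper bound only",
                TightBindingWarning, stacklevel=2)
        return self

    def predict(self, s1_tot_nm):
        return self.scale_ * bound_fraction_quadratic(
            np.asarray(s1_tot_nm, dtype=float), self.a0_nm, self.K_D_)


@dataclass(frozen=True)
class TitrationFit:
    K_D: float
    se_K_D: float
    scale: float
    se_scale: float
    tight_binding: bool


def fit_quadratic_titration(curve: TitrationCurve) -> TitrationFit:
    """Actin affinity (nM) from a transient-amplitude titration."""
    est = QuadraticTitrationFitter(a0_nm=curve.a0_nm).fit(
        curve.s1_tot_nm, curve.amplitude_pct)
    return TitrationFit(est.K_D_, est.se_K_D_, est.scale_, est.se_scale_,
                        est.tight_binding_)


# ---------------------------------------------------------------------
# Phase-assignment diagnostic
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseAssignment:
    """Outcome of the binding- vs hydrolysis-limited diagnostic.

    ``binding_pred_um`` is the half-saturating [ATP] expected if the fast
    phase reports the binding isomerisation (= 1/K1 = k_max / K1k2);
    ``hydrolysis_pred_um`` the value expected if it reports hydrolysis
    (kobs reaches k_max/2 where ``K1k2 [ATP] = k_max/2``).  The two
    differ by exactly a factor of 2, so the observed half-saturation
    discriminates between them.
    """

    diagnosis: str                  # "binding-limited" | "hydrolysis-limited"
                                    # | "indeterminate"
    binding_pred_um: float
    hydrolysis_pred_um: float
    observed_k_half_um: float
    half_max_rate: float            # k_max / 2, s⁻¹
    discrimination: float           # observed / hydrolysis prediction
    degenerate: bool                # slope was derived, not independent


def assign_fast_phase(k_max: float, k_half_obs: float,
                      K1k2: float) -> PhaseAssignment:
    """Decide whether the fast phase reports ATP binding or hydrolysis.

    All inputs must be positive; the diagnosis is ``"indeterminate"``
    when the observed half-saturation discriminates the two predictions
    by less than 10%, and flagged ``degenerate`` when the supplied
    second-order constant equals ``k_max/k_half_obs`` (the predictions
    then coincide with the observation by construction).
    """
    if min(k_max, k_half_obs, K1k2) <= 0:
        raise ValueError("all inputs must be > 0")
    binding_pred = k_max / K1k2
    hydrolysis_pred = k_max / (2.0 * K1k2)
    # degenerate when the slope equals k_max/k_half to printed precision,
    # i.e. it was derived from the same fit rather than measured
    degenerate = bool(abs(K1k2 - k_max / k_half_obs)
                      <= 1e-3 * (k_max / k_half_obs))
    d_bind = abs(math.log(k_half_obs / binding_pred))
    d_hyd = abs(math.log(k_half_obs / hydrolysis_pred))
    if abs(d_bind - d_hyd) < math.log(1.1):
        diagnosis = "indeterminate"
    elif d_bind < d_hyd:
        diagnosis = "binding-limited"
    else:
        diagnosis = "hydrolysis-limited"
    return PhaseAssignment(
        diagnosis=diagnosis,
        binding_pred_um=binding_pred,
        hydrolysis_pred_um=hydrolysis_pred,
        observed_k_half_um=k_half_obs,
        half_max_rate=k_max / 2.0,
        discrimination=k_half_obs / hydrolysis_pred,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------
# Derived constants and construct comparison
# ---------------------------------------------------------------------

@dataclass
class DerivedConstants:
    """Quantities computed from fitted primaries; every value equals its
    defining ratio of the stored inputs."""

    one_over_K1_um: Optional[float] = None
    detached_lifetime_ms: Optional[float] = None
    K_alpha: Optional[float] = None
    k_minus_alpha: Optional[float] = None
    K_DA_over_K_A: Optional[float] = None
    K_AD_over_K_D: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def derive_constants(primaries: dict) -> DerivedConstants:
    """Compute the derived-constant block from fitted primaries.

    Recognised keys: ``K1k2``, ``k_plus2``, ``k_slow`` (= k+3 + k−3),
    ``a_fast_pct``, ``a_slow_pct``, ``k_plus_alpha``, ``K_A``, ``K_DA``,
    ``K_AD``, ``K_D``.  Missing primaries simply leave the corresponding
    field unset.
    """
    out = DerivedConstants()
    if primaries.get("K1k2") and primaries.get("k_plus2"):
        out.one_over_K1_um = primaries["k_plus2"] / primaries["K1k2"]
    if primaries.get("k_slow"):
        out.detached_lifetime_ms = 1000.0 / primaries["k_slow"]
    if (primaries.get("a_fast_pct") is not None
            and primaries.get("a_slow_pct") is not None
            and primaries.get("k_plus_alpha")):
        out.K_alpha, out.k_minus_alpha = k_minus_alpha_from_amplitudes(
            primaries["a_fast_pct"], primaries["a_slow_pct"],
            primaries["k_plus_alpha"])
    if primaries.get("K_A") and primaries.get("K_DA"):
        out.K_DA_over_K_A = primaries["K_DA"] / primaries["K_A"]
    if primaries.get("K_D") and primaries.get("K_AD"):
        out.K_AD_over_K_D = primaries["K_AD"] / primaries["K_D"]
    return out


def compare_constructs(wt: pd.DataFrame, mutant: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-parameter comparison of two constructs over replicate preps.

    ``wt`` and ``mutant`` hold one row per protein preparation and one
    column per parameter.  Uses Welch's two-sample t-test (unequal
    variances are evident between constructs); with a single replicate
    on either side only the ratio of means is reported.
    """
    rows = []
    for col in wt.columns:
        if col not in mutant.columns:
            continue
        x = wt[col].dropna().to_numpy(dtype=float)
        y = mutant[col].dropna().to_numpy(dtype=float)
        if x.size == 0 or y.size == 0:
            continue
        mean_wt, mean_mut = float(np.mean(x)), float(np.mean(y))
        ratio = mean_mut / mean_wt if mean_wt != 0 else np.nan
        if x.size >= 2 and y.size >= 2:
            tol_x = 1e-12 * max(abs(mean_wt), 1e-300)
            tol_y = 1e-12 * max(abs(mean_mut), 1e-300)
            if np.std(x) <= tol_x and np.std(y) <= tol_y:
                # degenerate replicates (e.g. noiseless synthetic data)
                p = 1.0 if abs(mean_wt - mean_mut) <= tol_x + tol_y else 0.0
            else:
                p = float(scipy.stats.ttest_ind(x, y, equal_var=False).pvalue)
                if math.isnan(p):
                    p = 1.0 if mean_wt == mean_mut else 0.0
        else:
            p = np.nan
        rows.append({
            "parameter": col,
            "mean_wt": mean_wt, "sd_wt": float(np.std(x, ddof=1)) if x.size > 1 else np.nan,
            "mean_mut": mean_mut, "sd_mut": float(np.std(y, ddof=1)) if y.size > 1 else np.nan,
            "ratio_mut_over_wt": ratio,
            "p_value": p,
            "significant": bool(p < alpha) if not math.isnan(p) else False,
            "n_wt": int(x.size), "n_mut": int(y.size),
        })
    return pd.DataFrame(rows).set_index("parameter")


def detection_power(mean_wt: float, sd_wt: float, mean_mut: float,
                    sd_mut: float, n: int = 3, alpha: float = 0.05,
                    n_sim: int = 1000, seed: int = 0) -> float:
    """Monte-Carlo power of the Welch test to detect a parameter change.

    Draws ``n`` replicates per group from normal distributions with the
    given means/SDs, ``n_sim`` times, and returns the fraction of
    simulations with p < alpha.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sim):
        x = rng.normal(mean_wt, sd_wt, n)
        y = rng.normal(mean_mut, sd_mut, n)
        p = scipy.stats.ttest_ind(x, y, equal_var=False).pvalue
        hits += bool(p < alpha)
    return hits / n_sim
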