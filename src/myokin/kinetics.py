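"""Linear rate systems for the two stopped-flow schemes.

Under pseudo-first-order conditions (nucleotide in large excess over
protein) both schemes reduce to linear first-order systems
``dp/dt = Q p`` over a handful of states, where ``p`` is the vector of
state occupancies and ``Q`` a rate matrix whose columns sum to zero
(mass conservation).  The fluorescence observable is a yield-weighted
sum of occupancies, so every noiseless transient is exactly a sum of
exponentials whose rates are the negated eigenvalues of ``Q`` — this is
the analytic oracle the fitting modules are validated against.

Scheme 1 (S1 + ATP, tryptophan signal), rapid-equilibrium collapsed::

    M~M.T --a--> M*.T <--k±3--> M**.D.Pi --k_release--> products
    a = k_plus2 * K1[ATP] / (1 + K1[ATP])

Scheme 2 (acto·S1 + ATP/ADP, pyrene signal)::

    A.M' <--k±alpha--> A.M --kdiss--> A+M      (dissociation)
    A.M + D <--> A.M.D <--k±alphaD--> A.M'.D   (ADP branch)
    kdiss = k_plus2_prime * K1_prime[ATP] / (1 + K1_prime[ATP])
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import scipy.linalg

from .params import SchemeOneParams, SchemeTwoParams, AnyParams
from .trace import FluorescenceTrace, ObservableMap, trp_observables, pyrene_observables

__all__ = [
    "RateSystem",
    "build_rate_matrix",
    "scheme1_system",
    "scheme2_system",
    "scheme2_initial",
    "eigen_phases",
    "simulate_transient",
    "simulate_scheme1",
    "simulate_scheme2",
    "default_time_grid",
    "PseudoFirstOrderError",
]

#: minimum ligand excess over protein for the pseudo-first-order reduction
PFO_FACTOR = 10.0


class PseudoFirstOrderError(ValueError):
    """Ligand not in sufficient excess over protein."""


def _check_pfo(ligand_name: str, ligand_um: float,
               protein_um: Optional[float]) -> None:
    if protein_um is None or ligand_um == 0:
        return
    if ligand_um < PFO_FACTOR * protein_um:
        raise PseudoFirstOrderError(
            f"[{ligand_name}] = {ligand_um:g} μM is below "
            f"{PFO_FACTOR:g}x the protein concentration "
            f"({protein_um:g} μM); pseudo-first-order reduction invalid"
        )


@dataclass(frozen=True)
class RateSystem:
    """A rate matrix over named scheme states."""

    Q: np.ndarray
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.states)
        if self.Q.shape != (n, n):
            raise ValueError("rate matrix shape does not match state count")
        off = self.Q - np.diag(np.diag(self.Q))
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rate-matrix entries must be >= 0")
        colsums = self.Q.sum(axis=0)
        if np.any(np.abs(colsums) > 1e-10):
            raise ValueError("rate-matrix columns must sum to zero")

    def index(self, state: str) -> int:
        return self.states.index(state)


def _assemble(states: Sequence[str], edges: dict[tuple[str, str], float]) -> RateSystem:
    idx = {s: i for i, s in enumerate(states)}
    Q = np.zeros((len(states), len(states)))
    for (src, dst), rate in edges.items():
        if rate < 0:
            raise ValueError(f"negative rate for {src} -> {dst}")
        Q[idx[dst], idx[src]] += rate
        Q[idx[src], idx[src]] -= rate
    return RateSystem(Q, tuple(states))


def scheme1_system(params: SchemeOneParams, atp_um: float,
                   protein_um: Optional[float] = None,
                   explicit_binding: bool = False) -> RateSystem:
    """Rate system for S1 + ATP.

    With ``explicit_binding`` the rapid-equilibrium collapse of the first
    step is replaced by explicit on/off rates ``K1*k_minus1`` and
    ``k_minus1`` (used to validate the collapsed approximation).
    """
    if atp_um < 0:
        raise ValueError("ATP concentration must be >= 0")
    _check_pfo("ATP", atp_um, protein_um)
    if explicit_binding:
        states = ["M", "M.T", "M*.T", "M**.D.Pi", "products"]
        edges = {
            ("M", "M.T"): params.K1 * params.k_minus1 * atp_um,
            ("M.T", "M"): params.k_minus1,
            ("M.T", "M*.T"): params.k_plus2,
            ("M*.T", "M.T"): params.k_minus2,
            ("M*.T", "M**.D.Pi"): params.k_plus3,
            ("M**.D.Pi", "M*.T"): params.k_minus3,
            ("M**.D.Pi", "products"): params.k_release,
        }
    else:
        sat = params.K1 * atp_um / (1.0 + params.K1 * atp_um)
        states = ["M~M.T", "M*.T", "M**.D.Pi", "products"]
        edges = {
            ("M~M.T", "M*.T"): params.k_plus2 * sat,
            ("M*.T", "M~M.T"): params.k_minus2,
            ("M*.T", "M**.D.Pi"): params.k_plus3,
            ("M**.D.Pi", "M*.T"): params.k_minus3,
            ("M**.D.Pi", "products"): params.k_release,
        }
    return _assemble(states, edges)


SCHEME2_STATES = ("A.M'", "A.M", "A.M.D", "A.M'.D", "A+M")


def scheme2_system(params: SchemeTwoParams, atp_um: float,
                   adp_um: float = 0.0,
                   protein_um: Optional[float] = None) -> RateSystem:
    """Rate system for acto·S1 + ATP (+ ADP competition branch).

    ATP binding to A·M is a rapid equilibrium collapsed into the
    effective dissociation rate; the ADP branch is explicit, with the
    association rate ``k_minusAD / K_AD * [ADP]`` implied by the stored
    affinity and release rate.
    """
    if atp_um < 0 or adp_um < 0:
        raise ValueError("ligand concentrations must be >= 0")
    _check_pfo("ATP", atp_um, protein_um)
    _check_pfo("ADP", adp_um, protein_um)
    kdiss = params.k_plus2_prime * params.K1_prime * atp_um / (
        1.0 + params.K1_prime * atp_um)
    edges = {
        ("A.M'", "A.M"): params.k_plus_alpha,
        ("A.M", "A.M'"): params.k_minus_alpha,
        ("A.M", "A+M"): kdiss,
        ("A.M", "A.M.D"): params.k_minusAD / params.K_AD * adp_um,
        ("A.M.D", "A.M"): params.k_minusAD,
        ("A.M.D", "A.M'.D"): params.k_minus_alphaD,
        ("A.M'.D", "A.M.D"): params.k_plus_alphaD,
    }
    return _assemble(SCHEME2_STATES, edges)


def build_rate_matrix(params: AnyParams, atp_um: float = 0.0,
                      adp_um: float = 0.0,
                      protein_um: Optional[float] = None,
                      **kwargs) -> RateSystem:
    """Dispatch to the scheme matching the parameter type."""
    if isinstance(params, SchemeOneParams):
        if adp_um:
            raise ValueError("Scheme 1 simulator models the ATP pathway only")
        return scheme1_system(params, atp_um, protein_um=protein_um, **kwargs)
    if isinstance(params, SchemeTwoParams):
        return scheme2_system(params, atp_um, adp_um=adp_um,
                              protein_um=protein_um, **kwargs)
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


def scheme2_initial(params: SchemeTwoParams, system: RateSystem,
                    premix_adp_um: float = 0.0,
                    bound_fraction: float = 1.0) -> np.ndarray:
    """Pre-mix equilibrium occupancy of the actin·S1 states.

    The rigor pool partitions between A·M and A·M′ according to
    ``K_alpha``; with ADP in the pre-mix syringe the ADP-bound pair is
    populated according to ``K_AD`` and ``K_alphaD``.  ``bound_fraction``
    scales the complexed pool (the remainder starts as free pyrene-actin,
    as in titration experiments below stoichiometric S1).
    """
    w = {s: 0.0 for s in system.states}
    w["A.M"] = 1.0
    w["A.M'"] = 1.0 / params.K_alpha if np.isfinite(params.K_alpha) else 0.0
    if premix_adp_um > 0:
        w["A.M.D"] = premix_adp_um / params.K_AD
        w["A.M'.D"] = (w["A.M.D"] / params.K_alphaD
                       if np.isfinite(params.K_alphaD) else 0.0)
    p = np.array([w[s] for s in system.states])
    p = bound_fraction * p / p.sum()
    p[system.index("A+M")] = 1.0 - bound_fraction
    return p


# ---------------------------------------------------------------------
# Eigen-decomposition oracle and simulation
# ---------------------------------------------------------------------

def _eig_modes(system: RateSystem, p0: np.ndarray,
               yields: np.ndarray) -> tuple[float, list[tuple[float, float]]]:
    """Decompose the observable into exponential modes.

    Returns ``(offset, [(rate, coefficient), ...])`` such that
    ``signal(t) = offset + sum(coeff * exp(-rate * t))``, rates sorted
    descending.  Near-defective matrices fall back to a propagator-based
    decomposition with a warning.
    """
    w, V = np.linalg.eig(system.Q)
    if np.linalg.cond(V) > 1e10:
        # Documented jitter for (near-)degenerate eigenvalues: perturb the
        # diagonal by multiples of 1e-9 s^-1 to split coincident rates.
        warnings.warn(
            "near-defective rate matrix; applying 1e-9 s^-1 diagonal jitter",
            RuntimeWarning, stacklevel=3)
        n = system.Q.shape[0]
        w, V = np.linalg.eig(system.Q + np.diag(np.arange(n) * 1e-9))
    c = np.linalg.solve(V, p0.astype(complex))
    contrib = (yields @ V) * c  # per-mode signal coefficient
    offset = 0.0
    modes: list[tuple[float, float]] = []
    for lam, s in zip(w, contrib):
        rate = -float(np.real(lam))
        if abs(np.imag(lam)) > 1e-9 * max(1.0, abs(np.real(lam))):
            warnings.warn("complex eigenvalue encountered; taking real part",
                          RuntimeWarning, stacklevel=3)
        coeff = float(np.real(s))
        if abs(rate) < 1e-12:
            offset += coeff
        else:
            modes.append((rate, coeff))
    modes.sort(key=lambda rc: -rc[0])
    return offset, modes


def eigen_phases(params_or_system: Union[AnyParams, RateSystem],
                 atp_um: float = 0.0, adp_um: float = 0.0,
                 p0: Optional[np.ndarray] = None,
                 observables: Optional[ObservableMap] = None,
                 include_zero_amplitude: bool = False,
                 ) -> list[tuple[float, float]]:
    """Exponential phases (rate s⁻¹, signal coefficient) of a scheme.

    The coefficient is the signed weight of ``exp(-rate t)`` in the
    observable on the pre-mix fluorescence scale; the amplitude quoted by
    the fitting module is ``-coefficient * 100`` %.  Phases with
    negligible signal contribution are dropped unless
    ``include_zero_amplitude`` is set.
    """
    if isinstance(params_or_system, RateSystem):
        system = params_or_system
        params = None
    else:
        params = params_or_system
        system = build_rate_matrix(params, atp_um=atp_um, adp_um=adp_um)
    if p0 is None:
        p0 = default_initial(system, params)
    if observables is None:
        observables = default_observables(system)
    yields = observables.vector(system.states)
    _, modes = _eig_modes(system, np.asarray(p0, dtype=float), yields)
    if not include_zero_amplitude:
        scale = max(1e-12, max((abs(c) for _, c in modes), default=0.0))
        modes = [(r, c) for r, c in modes if abs(c) > 1e-9 * scale]
    return modes


def default_initial(system: RateSystem, params: Optional[AnyParams] = None) -> np.ndarray:
    """Pre-mix occupancy: apo myosin (Scheme 1) or rigor pool (Scheme 2)."""
    p0 = np.zeros(len(system.states))
    if system.states[0] in ("M", "M~M.T"):
        p0[0] = 1.0
        return p0
    if isinstance(params, SchemeTwoParams):
        return scheme2_initial(params, system)
    # rigor pool without parameter info: all in A.M
    p0[system.index("A.M")] = 1.0
    return p0


def default_observables(system: RateSystem) -> ObservableMap:
    return trp_observables() if system.states[0] in ("M", "M~M.T") \
        else pyrene_observables()


def default_time_grid(slowest_rate: float, dead_time: float = 0.0015,
                      n_points: int = 1000, spacing: str = "log") -> np.ndarray:
    """Log-spaced grid from the instrument dead time to 20/(slowest rate)."""
    if slowest_rate <= 0:
        raise ValueError("slowest_rate must be > 0")
    t_end = 20.0 / slowest_rate
    t0 = max(dead_time, 1e-6)
    if spacing == "log":
        return np.geomspace(t0, max(t_end, 2 * t0), n_points)
    return np.linspace(t0, max(t_end, 2 * t0), n_points)


def simulate_transient(params_or_system: Union[AnyParams, RateSystem],
                       atp_um: float = 0.0, adp_um: float = 0.0,
                       observables: Optional[ObservableMap] = None,
                       t_grid: Optional[np.ndarray] = None,
                       p0: Optional[np.ndarray] = None,
                       protein_um: Optional[float] = None,
                       method: str = "eigen",
                       meta: Optional[dict] = None) -> FluorescenceTrace:
    """Simulate a noiseless fluorescence transient.

    ``method`` selects the analytic eigen-decomposition path (default) or
    a matrix-exponential propagator (``"expm"``, the brute-force oracle).
    """
    if isinstance(params_or_system, RateSystem):
        system = params_or_system
        params = None
    else:
        params = params_or_system
        system = build_rate_matrix(params, atp_um=atp_um, adp_um=adp_um,
                                   protein_um=protein_um)
    if p0 is None:
        p0 = default_initial(system, params)
    p0 = np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("initial occupancies must sum to 1")
    if observables is None:
        observables = default_observables(system)
    yields = observables.vector(system.states)
    if t_grid is None:
        # span the slowest phase that would actually be resolvable
        # (>= 2% of the total signal change), not sub-resolution drift
        modes = eigen_phases(system, p0=p0, observables=observables)
        total = sum(abs(c) for _, c in modes)
        rates = [r for r, c in modes if abs(c) >= 0.02 * total]
        slowest = min(rates) if rates else 1.0
        t_grid = default_time_grid(slowest)
    t_grid = np.asarray(t_grid, dtype=float)

    if method == "eigen":
        offset, modes = _eig_modes(system, p0, yields)
        signal = np.full_like(t_grid, offset)
        for rate, coeff in modes:
            signal = signal + coeff * np.exp(-rate * t_grid)
    elif method == "expm":
        signal = np.empty_like(t_grid)
        for i, t in enumerate(t_grid):
            p = scipy.linalg.expm(system.Q * t) @ p0
            if abs(p.sum() - 1.0) > 1e-9:
                raise RuntimeError("occupancy conservation violated")
            signal[i] = yields @ p
    else:
        raise ValueError(f"unknown method {method!r}")

    info = {"atp_um": atp_um, "adp_um": adp_um, "states": list(system.states)}
    if meta:
        info.update(meta)
    return FluorescenceTrace(t_grid, signal, info)


def simulate_scheme1(params: SchemeOneParams, atp_um: float,
                     observables: Optional[ObservableMap] = None,
                     t_grid: Optional[np.ndarray] = None,
                     protein_um: Optional[float] = 0.2,
                     **kwargs) -> FluorescenceTrace:
    """Tryptophan transient for S1 mixed with ATP."""
    if observables is None:
        observables = trp_observables()
    meta = kwargs.pop("meta", {})
    meta.setdefault("probe", "tryptophan")
    return simulate_transient(params, atp_um=atp_um, observables=observables,
                              t_grid=t_grid, protein_um=protein_um,
                              meta=meta, **kwargs)


def simulate_scheme2(params: SchemeTwoParams, atp_um: float,
                     adp_um: float = 0.0, premix_adp_um: float = 0.0,
                     bound_fraction: float = 1.0,
                     observables: Optional[ObservableMap] = None,
                     t_grid: Optional[np.ndarray] = None,
                     protein_um: Optional[float] = 0.05,
                     **kwargs) -> FluorescenceTrace:
    """Pyrene-actin transient for actin·S1 mixed with ATP (± ADP)."""
    system = scheme2_system(params, atp_um, adp_um=adp_um,
                            protein_um=protein_um)
    p0 = kwargs.pop("p0", None)
    if p0 is None:
        p0 = scheme2_initial(params, system, premix_adp_um=premix_adp_um,
                             bound_fraction=bound_fraction)
    if observables is None:
        observables = pyrene_observables()
    meta = kwargs.pop("meta", {})
    meta.setdefault("probe", "pyrene-actin")
    return simulate_transient(system, observables=observables, t_grid=t_grid,
                              p0=p0, meta={**meta, "atp_um": atp_um,
                                           "adp_um": adp_um}, **kwargs)
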