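"""Kinetic parameter sets for the myosin S1 / acto·S1 reaction schemes.

Two schemes are modelled throughout the package:

* **Scheme 1** — nucleotide binding to the isolated S1 motor domain
  (tryptophan signal).  ATP binding is a rapid equilibrium (association
  constant ``K1``) followed by an essentially irreversible isomerisation
  ``k_plus2`` that carries the large fluorescence change, then the
  hydrolysis / recovery-stroke step ``k_plus3 + k_minus3`` and a slow
  lumped product-release exit.

* **Scheme 2** — nucleotide binding to the actin·S1 (rigor) complex
  (pyrene-actin signal).  The complex exists in two conformers, A·M′ and
  A·M, in equilibrium; only A·M binds nucleotide.  ATP binding (rapid
  equilibrium ``K1_prime``) is followed by the dissociating isomerisation
  ``k_plus2_prime``.  A parallel pair of conformers exists with ADP bound
  (A·M′·D ⇌ A·M·D), from which ADP is released at ``k_minusAD``.

Units are fixed package-wide: association constants in μM⁻¹, dissociation
constants in μM (actin affinities in nM), first-order rates in s⁻¹.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "SchemeOneParams",
    "SchemeTwoParams",
    "load_params",
    "save_params",
    "PRESETS",
]


class _FrozenModel(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class SchemeOneParams(_FrozenModel):
    """Rate and equilibrium constants for S1 + nucleotide (Scheme 1).

    Attributes
    ----------
    K1 : float
        Rapid-equilibrium ATP association constant, μM⁻¹.
    k_plus2, k_minus2 : float
        Forward/reverse rate of the fluorescence-reporting isomerisation
        after ATP binding, s⁻¹.  ``k_minus2`` defaults to 0 (step 2 is
        irreversible for muscle myosin II).
    k_plus3, k_minus3 : float
        Forward/reverse rate of the ATP hydrolysis step (coupled to the
        recovery stroke), s⁻¹.  Only the sum is observable as the slow
        phase of the tryptophan transient.
    k_release : float
        Lumped product-release rate terminating the cycle, s⁻¹.  Basal
        turnover is of order 0.05 s⁻¹ and irrelevant on the observed
        0–5 s window.
    K_D : float
        ADP dissociation constant for S1, μM.
    k_minusD : float
        ADP release rate from S1·ADP, s⁻¹.
    k_minus1 : float
        ATP off-rate used only by the explicit-binding (non-collapsed)
        variant of the simulator; the matching on-rate is ``K1 * k_minus1``.
    """

    K1: float
    k_plus2: float
    k_minus2: float = 0.0
    k_plus3: float
    k_minus3: float
    k_release: float = 0.05
    K_D: float = 1.0
    k_minusD: float = 0.56
    k_minus1: float = 1.0e4

    @field_validator("K1")
    @classmethod
    def _positive_K1(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("K1 must be > 0")
        return v

    @field_validator(
        "k_plus2", "k_minus2", "k_plus3", "k_minus3", "k_release",
        "K_D", "k_minusD", "k_minus1",
    )
    @classmethod
    def _nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("rate constants must be >= 0")
        return v

    @model_validator(mode="after")
    def _invariants(self) -> "SchemeOneParams":
        if self.k_minus2 > 0.1 * self.k_plus2:
            raise ValueError(
                "k_minus2 must be small relative to k_plus2 "
                "(step 2 is effectively irreversible)"
            )
        if self.k_release >= self.k_plus3 + self.k_minus3:
            raise ValueError("k_release must be < k_plus3 + k_minus3")
        return self

    @property
    def K1k2(self) -> float:
        """Apparent second-order ATP binding constant K1*k_plus2, μM⁻¹s⁻¹."""
        return self.K1 * self.k_plus2

    @property
    def one_over_K1(self) -> float:
        """Half-saturating ATP concentration 1/K1, μM."""
        return 1.0 / self.K1

    @property
    def k_slow(self) -> float:
        """Observable hydrolysis-phase plateau k_plus3 + k_minus3, s⁻¹."""
        return self.k_plus3 + self.k_minus3


class SchemeTwoParams(_FrozenModel):
    """Rate and equilibrium constants for acto·S1 + nucleotide (Scheme 2).

    ``k_plus_alpha`` is the A·M′ → A·M isomerisation (slow-phase plateau of
    the ATP-induced dissociation), ``k_minus_alpha`` its reverse; the
    equilibrium constant ``K_alpha = k_plus_alpha / k_minus_alpha`` equals
    the fast/slow amplitude ratio.  The ADP branch mirrors this with
    ``k_plus_alphaD``/``k_minus_alphaD`` and the release rate ``k_minusAD``.
    """

    K1_prime: float
    k_plus2_prime: float
    k_plus_alpha: float
    k_minus_alpha: float
    K_AD: float = 13.0
    k_minusAD: float = 63.0
    k_plus_alphaD: float = 2.0
    k_minus_alphaD: float = 0.25
    K_A: float = 11.0
    K_DA: float = 472.0

    @field_validator("K1_prime", "K_AD", "K_A", "K_DA")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("equilibrium constants must be > 0")
        return v

    @field_validator(
        "k_plus2_prime", "k_plus_alpha", "k_minus_alpha",
        "k_minusAD", "k_plus_alphaD", "k_minus_alphaD",
    )
    @classmethod
    def _nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("rate constants must be >= 0")
        return v

    @property
    def K1k2_prime(self) -> float:
        """Apparent second-order ATP binding constant to A·M, μM⁻¹s⁻¹."""
        return self.K1_prime * self.k_plus2_prime

    @property
    def one_over_K1_prime(self) -> float:
        """Half-saturating ATP concentration 1/K′1, μM."""
        return 1.0 / self.K1_prime

    @property
    def K_alpha(self) -> float:
        """Conformer equilibrium [A·M]/[A·M′] = k_plus_alpha/k_minus_alpha."""
        if self.k_minus_alpha == 0:
            return float("inf")
        return self.k_plus_alpha / self.k_minus_alpha

    @property
    def K_alphaD(self) -> float:
        """ADP-bound conformer equilibrium [A·M·D]/[A·M′·D]."""
        if self.k_minus_alphaD == 0:
            return float("inf")
        return self.k_plus_alphaD / self.k_minus_alphaD


AnyParams = Union[SchemeOneParams, SchemeTwoParams]


def save_params(params: AnyParams, path: Union[str, Path]) -> None:
    """Write a parameter set as a JSON document keyed by symbol names."""
    doc = {"scheme": 1 if isinstance(params, SchemeOneParams) else 2}
    doc.update(params.model_dump())
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_params(path: Union[str, Path]) -> AnyParams:
    """Read a parameter set written by :func:`save_params`.

    The scheme is taken from the explicit ``scheme`` key when present,
    otherwise inferred from the field names.
    """
    doc = json.loads(Path(path).read_text())
    scheme = doc.pop("scheme", None)
    if scheme is None:
        scheme = 2 if "K1_prime" in doc else 1
    cls = SchemeOneParams if int(scheme) == 1 else SchemeTwoParams
    return cls(**doc)


# --- Published parameter sets used as generator inputs -------------------
#
# "fig" sets carry the single-experiment fitted constants from the
# concentration-dependence figures; the conformer-branch and ADP-branch
# constants come from the replicate-mean summary table.  K1 is stored as
# the quotient of the printed apparent second-order constant and the
# printed plateau, so the pair (initial slope, k_max) is internally
# consistent.

S1_WT = SchemeOneParams(
    K1=1.5 / 137.0, k_plus2=137.0, k_plus3=11.2, k_minus3=2.8,
    K_D=1.0, k_minusD=0.56,
)
S1_R453C = SchemeOneParams(
    K1=1.08 / 88.0, k_plus2=88.0, k_plus3=3.2, k_minus3=0.8,
    K_D=0.7, k_minusD=0.59,
)
ACTO_S1_WT = SchemeTwoParams(
    K1_prime=1.6 / 1081.0, k_plus2_prime=1081.0,
    k_plus_alpha=49.0, k_minus_alpha=49.0 / 12.0,
    K_AD=10.0, k_minusAD=64.0,
    k_plus_alphaD=1.8, k_minus_alphaD=1.8 / 3.7,
    K_A=8.0, K_DA=190.0,
)
ACTO_S1_R453C = SchemeTwoParams(
    K1_prime=1.0 / 891.0, k_plus2_prime=1357.0,
    k_plus_alpha=69.0, k_minus_alpha=69.0 / 11.0,
    K_AD=13.0, k_minusAD=63.0,
    k_plus_alphaD=2.0, k_minus_alphaD=0.25,
    K_A=11.0, K_DA=472.0,
)

PRESETS: dict[str, AnyParams] = {
    "S1_WT": S1_WT,
    "S1_R453C": S1_R453C,
    "ACTO_S1_WT": ACTO_S1_WT,
    "ACTO_S1_R453C": ACTO_S1_R453C,
}


def get_preset(name: str) -> AnyParams:
    """Look up a bundled parameter set by name (case-insensitive)."""
    key = name.upper()
    if key not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    return PRESETS[key]
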