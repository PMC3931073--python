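"""Seeded synthetic stopped-flow experiments.

No raw transients from the source study are deposited, so this module
generates them: for any parameter set it emulates the five experiment
designs of the study — tryptophan ATP titration on S1, pyrene-actin
ATP-induced dissociation of acto·S1, ADP/ATP competition, ADP
displacement, and actin-affinity titrations — with instrument dead time
and additive Gaussian noise.

Reproducibility: every experiment derives per-trace random streams from
a master seed via ``numpy.random.SeedSequence.spawn``, so identical
seeds give bit-identical traces and replicate streams are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .params import SchemeOneParams, SchemeTwoParams, AnyParams
from .trace import FluorescenceTrace, trp_observables, pyrene_observables
from .kinetics import (default_time_grid, scheme2_system, scheme2_initial,
                       simulate_scheme1, simulate_scheme2, simulate_transient)
from .analysis import bound_fraction_quadratic

__all__ = [
    "InstrumentModel",
    "ExperimentDesign",
    "Experiment",
    "generate_experiment",
    "battery",
    "DESIGN_KINDS",
    "CV_TABLE",
]

DESIGN_KINDS = (
    "trp_atp_titration",
    "pyrene_atp_dissociation",
    "adp_competition",
    "adp_displacement",
    "actin_titration",
)

#: relative ATP grid for the titration designs, in units of the
#: half-saturating concentration (spans the linear regime to >= 4x K_half)
REL_ATP_GRID = (0.05, 0.1, 0.25, 0.5, 1.0, 1.5, 2.5, 4.0)

#: ADP grid for the competition design, μM (mixing with 20 μM ATP)
ADP_GRID_UM = (0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 50.0, 75.0, 100.0)

#: S1 grids for the actin titrations, nM (actin fixed at 30 nM)
S1_GRID_NM = (5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 80.0, 110.0, 160.0)
S1_GRID_ADP_NM = (10.0, 25.0, 50.0, 100.0, 200.0, 400.0, 700.0, 1100.0, 1600.0)


class InstrumentModel(BaseModel):
    """Stopped-flow instrument characteristics.

    ``dead_time_s`` truncates the start of every record (handled by
    discarding, not convolution); ``noise_sd_pct`` is additive iid
    Gaussian noise as a percentage of the pre-mix fluorescence (0.5% is
    a typical photomultiplier figure; the study does not report one).
    """

    model_config = ConfigDict(frozen=True)

    dead_time_s: float = 0.0015
    noise_sd_pct: float = 0.5
    n_points: int = 1000
    spacing: Literal["log", "linear"] = "log"

    @field_validator("dead_time_s", "noise_sd_pct")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("must be >= 0")
        return v


class ExperimentDesign(BaseModel):
    """One of the five stopped-flow experiment designs.

    Concentration grids default to the study's post-mix ranges for the
    given kind; ``atp_grid_um=None`` on the titration designs means
    "relative grid scaled by the parameter set's 1/K1".
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal[
        "trp_atp_titration",
        "pyrene_atp_dissociation",
        "adp_competition",
        "adp_displacement",
        "actin_titration",
    ]
    atp_grid_um: Optional[tuple[float, ...]] = None
    adp_grid_um: tuple[float, ...] = ADP_GRID_UM
    s1_grid_nm: Optional[tuple[float, ...]] = None
    protein_um: float = 0.2          # post-mix S1 (trp) / acto·S1 (pyrene)
    actin_nm: float = 30.0           # fixed actin in the titration design
    competition_atp_um: float = 20.0
    displacement_atp_um: float = 2000.0
    displacement_premix_adp_um: float = 50.0
    titration_adp_um: float = 100.0  # ADP present in the K_DA titration
    with_adp: bool = False           # actin_titration: measure K_DA?


@dataclass
class Experiment:
    """Generated traces plus the ground-truth record used for scoring."""

    design: ExperimentDesign
    traces: list[FluorescenceTrace]
    truth: dict


def _atp_grid(design: ExperimentDesign, params: AnyParams) -> np.ndarray:
    if design.atp_grid_um is not None:
        return np.asarray(design.atp_grid_um, dtype=float)
    if isinstance(params, SchemeOneParams):
        k_half = params.one_over_K1
    else:
        k_half = params.one_over_K1_prime
    return k_half * np.asarray(REL_ATP_GRID)


def _noise(rng: np.random.Generator, n: int, sd_pct: float) -> np.ndarray:
    if sd_pct == 0:
        return np.zeros(n)
    return rng.normal(0.0, sd_pct / 100.0, n)


def _time_grid(slowest: float, instrument: InstrumentModel,
               spacing: Optional[str] = None) -> np.ndarray:
    """Sampling grid for one record.

    Designs whose records span well-separated phases use the instrument's
    (default log) spacing, emulating a split time base; single-exponential
    designs pass ``spacing="linear"``, the ordinary stopped-flow time base.
    """
    return default_time_grid(slowest, dead_time=instrument.dead_time_s,
                             n_points=instrument.n_points,
                             spacing=spacing or instrument.spacing)


def generate_experiment(design: ExperimentDesign, params: AnyParams,
                        instrument: Optional[InstrumentModel] = None,
                        seed: int = 0) -> Experiment:
    """Generate the synthetic traces for one experiment design.

    Identical ``seed`` gives bit-identical output.  Every trace carries
    the generating truth in its metadata (stripped on text export).
    """
    instrument = instrument or InstrumentModel()
    root = np.random.SeedSequence(seed)
    kind = design.kind

    if kind == "trp_atp_titration":
        if not isinstance(params, SchemeOneParams):
            raise TypeError("trp_atp_titration requires SchemeOneParams")
        return _gen_trp(design, params, instrument, root, seed)
    if not isinstance(params, SchemeTwoParams):
        raise TypeError(f"{kind} requires SchemeTwoParams")
    if kind == "pyrene_atp_dissociation":
        return _gen_pyrene(design, params, instrument, root, seed)
    if kind == "adp_competition":
        return _gen_competition(design, params, instrument, root, seed)
    if kind == "adp_displacement":
        return _gen_displacement(design, params, instrument, root, seed)
    if kind == "actin_titration":
        return _gen_titration(design, params, instrument, root, seed)
    raise ValueError(f"unknown design kind {kind!r}")


def _finish(trace: FluorescenceTrace, rng: np.random.Generator,
            instrument: InstrumentModel, truth: dict, seed: int,
            extra: dict) -> FluorescenceTrace:
    noisy = trace.signal + _noise(rng, len(trace), instrument.noise_sd_pct)
    meta = dict(trace.meta)
    meta.update(extra)
    meta.update({
        "seed": seed,
        "noise_sd_pct": instrument.noise_sd_pct,
        "dead_time_s": instrument.dead_time_s,
        "temperature": "20C",
        "truth": truth,
    })
    return FluorescenceTrace(trace.time, noisy, meta)


def _gen_trp(design, params: SchemeOneParams, instrument, root, seed):
    grid = _atp_grid(design, params)
    truth = {"scheme": 1, "params": params.model_dump(),
             "k_slow": params.k_slow, "K1k2": params.K1k2}
    traces = []
    for atp, ss in zip(grid, root.spawn(len(grid))):
        rng = np.random.default_rng(ss)
        fast = params.k_plus2 * params.K1 * atp / (1 + params.K1 * atp)
        t = _time_grid(0.8 * min(params.k_slow, max(fast, 1e-3)), instrument)
        tr = simulate_scheme1(params, atp, t_grid=t,
                              protein_um=design.protein_um)
        traces.append(_finish(tr, rng, instrument, truth, seed,
                              {"design": design.kind, "atp_um": atp}))
    return Experiment(design, traces, truth)


def _gen_pyrene(design, params: SchemeTwoParams, instrument, root, seed):
    grid = _atp_grid(design, params)
    truth = {"scheme": 2, "params": params.model_dump(),
             "K1k2_prime": params.K1k2_prime}
    protein = design.protein_um if design.protein_um else 0.05
    traces = []
    for atp, ss in zip(grid, root.spawn(len(grid))):
        rng = np.random.default_rng(ss)
        kdiss = params.K1k2_prime * atp / (1 + params.K1_prime * atp)
        slowest = 0.8 * min(params.k_plus_alpha, max(kdiss, 1e-3))
        t = _time_grid(slowest, instrument)
        tr = simulate_scheme2(params, atp, t_grid=t, protein_um=protein)
        traces.append(_finish(tr, rng, instrument, truth, seed,
                              {"design": design.kind, "atp_um": atp}))
    return Experiment(design, traces, truth)


def _gen_competition(design, params: SchemeTwoParams, instrument, root, seed):
    atp = design.competition_atp_um
    kdiss0 = params.K1k2_prime * atp / (1 + params.K1_prime * atp)
    truth = {"scheme": 2, "params": params.model_dump(),
             "K_AD": params.K_AD, "kobs0": kdiss0}
    traces = []
    grid = np.asarray(design.adp_grid_um, dtype=float)
    for adp, ss in zip(grid, root.spawn(len(grid))):
        rng = np.random.default_rng(ss)
        slowest = max(kdiss0 / (1 + adp / params.K_AD), 0.5)
        t = _time_grid(slowest, instrument, spacing="linear")
        tr = simulate_scheme2(params, atp, adp_um=adp, t_grid=t,
                              protein_um=0.1)
        traces.append(_finish(tr, rng, instrument, truth, seed,
                              {"design": design.kind, "atp_um": atp,
                               "adp_um": adp}))
    return Experiment(design, traces, truth)


def _gen_displacement(design, params: SchemeTwoParams, instrument, root, seed):
    atp = design.displacement_atp_um
    post_adp = design.displacement_premix_adp_um / 2.0  # 1:1 mixing
    truth = {"scheme": 2, "params": params.model_dump(),
             "k_minusAD": params.k_minusAD,
             "k_plus_alphaD": params.k_plus_alphaD,
             "K_alphaD": params.K_alphaD}
    t = _time_grid(params.k_plus_alphaD, instrument)
    rng = np.random.default_rng(root.spawn(1)[0])
    tr = simulate_scheme2(params, atp, adp_um=post_adp,
                          premix_adp_um=design.displacement_premix_adp_um,
                          t_grid=t, protein_um=0.1)
    traces = [_finish(tr, rng, instrument, truth, seed,
                      {"design": design.kind, "atp_um": atp,
                       "adp_um": post_adp})]
    return Experiment(design, traces, truth)


def _gen_titration(design, params: SchemeTwoParams, instrument, root, seed):
    a0 = design.actin_nm
    with_adp = design.with_adp
    kd = params.K_DA if with_adp else params.K_A
    grid = np.asarray(
        design.s1_grid_nm if design.s1_grid_nm is not None
        else (S1_GRID_ADP_NM if with_adp else S1_GRID_NM), dtype=float)
    atp = 500.0 if with_adp else 20.0
    premix_adp = 2 * design.titration_adp_um if with_adp else 0.0
    adp = design.titration_adp_um if with_adp else 0.0
    truth = {"scheme": 2, "params": params.model_dump(),
             "K_D": kd, "a0_nm": a0, "with_adp": with_adp}
    traces = []
    for m, ss in zip(grid, root.spawn(len(grid))):
        rng = np.random.default_rng(ss)
        alpha = float(bound_fraction_quadratic(np.array([m]), a0, kd)[0])
        kdiss = params.K1k2_prime * atp / (1 + params.K1_prime * atp)
        kobs_eff = kdiss / (1 + adp / params.K_AD) if adp else kdiss
        t = _time_grid(max(kobs_eff, 1.0), instrument, spacing="linear")
        tr = simulate_scheme2(params, atp, adp_um=adp,
                              premix_adp_um=premix_adp,
                              bound_fraction=alpha, t_grid=t,
                              protein_um=max(m, 1.0) / 1000.0)
        traces.append(_finish(tr, rng, instrument, truth, seed,
                              {"design": design.kind, "atp_um": atp,
                               "adp_um": adp, "s1_tot_nm": m,
                               "actin_nm": a0, "bound_fraction": alpha}))
    return Experiment(design, traces, truth)


# ---------------------------------------------------------------------
# Full battery with inter-preparation variability
# ---------------------------------------------------------------------

#: coefficient of variation of each parameter across protein
#: preparations, taken from the replicate-mean summary (SD/mean);
#: parameters reported without an SD get the 10% default.
CV_TABLE = {
    "K1": 0.10, "k_plus2": 0.14, "k_plus3": 0.10, "k_minus3": 0.10,
    "K1_prime": 0.16, "k_plus2_prime": 0.08,
    "k_plus_alpha": 0.27, "k_minus_alpha": 0.17,
    "K_AD": 0.31, "k_minusAD": 0.04,
    "k_plus_alphaD": 0.06, "k_minus_alphaD": 0.11,
    "K_A": 0.45, "K_DA": 0.60,
    "K_D": 0.10, "k_minusD": 0.14,
}
CV_DEFAULT = 0.10

_PERTURB_FIELDS_1 = ("K1", "k_plus2", "k_plus3", "k_minus3", "K_D", "k_minusD")
_PERTURB_FIELDS_2 = ("K1_prime", "k_plus2_prime", "k_plus_alpha",
                     "k_minus_alpha", "K_AD", "k_minusAD", "k_plus_alphaD",
                     "k_minus_alphaD", "K_A", "K_DA")


def perturb_params(params: AnyParams, rng: np.random.Generator,
                   cv_scale: float = 1.0) -> AnyParams:
    """Lognormal multiplicative perturbation emulating prep-to-prep
    variability, with per-parameter CVs from :data:`CV_TABLE`."""
    fields = (_PERTURB_FIELDS_1 if isinstance(params, SchemeOneParams)
              else _PERTURB_FIELDS_2)
    updates = {}
    for name in fields:
        cv = CV_TABLE.get(name, CV_DEFAULT) * cv_scale
        if cv == 0:
            continue
        sigma = np.sqrt(np.log1p(cv * cv))
        updates[name] = getattr(params, name) * float(
            rng.lognormal(-0.5 * sigma * sigma, sigma))
    return params.model_copy(update=updates)


@dataclass
class Preparation:
    """One synthetic protein preparation: perturbed truth + experiments."""

    construct: str
    index: int
    s1_params: SchemeOneParams
    acto_params: SchemeTwoParams
    experiments: dict[str, Experiment]


@dataclass
class Battery:
    """A complete synthetic study: designs x constructs x preparations."""

    seed: int
    preparations: dict[str, list[Preparation]]

    def truth_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "preparations": {
                construct: [
                    {"index": p.index,
                     "s1_params": p.s1_params.model_dump(),
                     "acto_params": p.acto_params.model_dump()}
                    for p in preps
                ]
                for construct, preps in self.preparations.items()
            },
        }


def default_designs(with_titrations: bool = True) -> list[ExperimentDesign]:
    designs = [
        ExperimentDesign(kind="trp_atp_titration"),
        ExperimentDesign(kind="pyrene_atp_dissociation", protein_um=0.05),
        ExperimentDesign(kind="adp_competition"),
        ExperimentDesign(kind="adp_displacement"),
    ]
    if with_titrations:
        designs.append(ExperimentDesign(kind="actin_titration", with_adp=False))
        designs.append(ExperimentDesign(kind="actin_titration", with_adp=True))
    return designs


def battery(s1_wt: SchemeOneParams, acto_wt: SchemeTwoParams,
            s1_mut: SchemeOneParams, acto_mut: SchemeTwoParams,
            seed: int = 42, n_preps: int = 3, cv_scale: float = 1.0,
            instrument: Optional[InstrumentModel] = None,
            designs: Optional[Sequence[ExperimentDesign]] = None) -> Battery:
    """Generate the complete synthetic study for two constructs.

    Each of ``n_preps`` "protein preparations" gets an independently
    perturbed parameter set (lognormal, CVs per parameter) and a full set
    of experiment designs.  ``cv_scale=0`` disables inter-preparation
    variability.
    """
    instrument = instrument or InstrumentModel()
    designs = list(designs) if designs is not None else default_designs()
    root = np.random.SeedSequence(seed)
    construct_params = {
        "WT": (s1_wt, acto_wt),
        "R453C": (s1_mut, acto_mut),
    }
    preparations: dict[str, list[Preparation]] = {}
    for (construct, (s1p, actop)), cseq in zip(
            construct_params.items(), root.spawn(2)):
        preps = []
        for i, pseq in enumerate(cseq.spawn(n_preps)):
            perturb_seq, exp_seq = pseq.spawn(2)
            rng = np.random.default_rng(perturb_seq)
            s1_i = perturb_params(s1p, rng, cv_scale)
            acto_i = perturb_params(actop, rng, cv_scale)
            experiments = {}
            for design, dseq in zip(designs, exp_seq.spawn(len(designs))):
                p = s1_i if design.kind == "trp_atp_titration" else acto_i
                key = design.kind + ("_adp" if getattr(design, "with_adp", False)
                                     and design.kind == "actin_titration" else "")
                experiments[key] = generate_experiment(
                    design, p, instrument,
                    seed=int(dseq.generate_state(1)[0] % (2 ** 31)))
            preps.append(Preparation(construct, i, s1_i, acto_i, experiments))
        preparations[construct] = preps
    return Battery(seed=seed, preparations=preparations)
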