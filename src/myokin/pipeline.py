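"""Orchestration: fit whole experiments and build the comparison report.

The full chain is

    synthetic experiments (synth) -> per-trace exponential fits (expfit)
    -> concentration-dependence / titration fits (analysis)
    -> per-preparation parameter estimates
    -> per-construct mean ± SD, mutant/WT ratios and Welch flags

mirroring how the stopped-flow study assembles its summary table from
individual records.  Phase labelling follows experimental practice: the
phase with the dominant amplitude is the principal ("fast") phase of a
record; where two phases resolve, the smaller-amplitude one is the slow
phase.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import analysis as an
from .expfit import ExponentialTransientFitter, ExpFitResult
from .params import (AnyParams, SchemeOneParams, SchemeTwoParams,
                     PRESETS, get_preset, load_params)
from .synth import (Battery, ExperimentDesign, Experiment, InstrumentModel,
                    battery, default_designs)
from .trace import FluorescenceTrace, read_trace, write_trace

logger = logging.getLogger("myokin")

__all__ = [
    "BatteryConfig",
    "PipelineError",
    "analyze_trp_titration",
    "analyze_pyrene_dissociation",
    "analyze_adp_competition",
    "analyze_adp_displacement",
    "analyze_actin_titration",
    "analyze_preparation",
    "run_battery",
    "fit_file",
    "write_series",
    "read_series",
    "REPORT_ROWS",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed in a way that invalidates the report."""


# ---------------------------------------------------------------------
# Series text I/O (delimited text with a # header block)
# ---------------------------------------------------------------------

def write_series(series: an.KobsSeries, path: Union[str, Path],
                 meta: Optional[dict] = None) -> None:
    lines = [
        "# myokin-series v1",
        "# meta: " + json.dumps({"ligand": series.ligand,
                                 "phase": series.phase, **(meta or {})},
                                default=float),
        "# columns: conc_um\tkobs_s\tamplitude_pct",
    ]
    amp = (series.amplitude_pct if series.amplitude_pct is not None
           else np.full(len(series), np.nan))
    for c, k, a in zip(series.conc_um, series.kobs, amp):
        lines.append(f"{c:.6g}\t{k:.8g}\t{a:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_series(path: Union[str, Path]) -> an.KobsSeries:
    meta: dict = {}
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("meta:"):
                meta = json.loads(body[len("meta:"):])
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        rows.append([float(x) for x in parts])
    arr = np.array(rows)
    amp = arr[:, 2]
    return an.KobsSeries(
        ligand=meta.get("ligand", "ATP"), conc_um=arr[:, 0], kobs=arr[:, 1],
        amplitude_pct=None if np.all(np.isnan(amp)) else amp,
        phase=meta.get("phase", "fast"))


# ---------------------------------------------------------------------
# Per-design analyses
# ---------------------------------------------------------------------

@dataclass
class PhaseRecord:
    """Per-trace fit bookkeeping for provenance."""

    conc_um: float
    fit: ExpFitResult


def _fit_traces(traces: Sequence[FluorescenceTrace], conc_key: str,
                n_phases="auto") -> list[PhaseRecord]:
    records = []
    for tr in traces:
        fit = ExponentialTransientFitter(n_phases=n_phases).fit(tr).result_
        records.append(PhaseRecord(float(tr.meta[conc_key]), fit))
    return records


def _split_phases(records: list[PhaseRecord]):
    """Dominant-amplitude ("fast") and secondary ("slow") phase arrays."""
    conc, kf, af, ks, asl = [], [], [], [], []
    for rec in sorted(records, key=lambda r: r.conc_um):
        dom = rec.fit.dominant_phase
        conc.append(rec.conc_um)
        kf.append(dom.kobs)
        af.append(dom.amplitude_pct)
        others = [p for p in rec.fit.phases if p is not dom]
        if others:
            ks.append(others[0].kobs)
            asl.append(others[0].amplitude_pct)
        else:
            ks.append(np.nan)
            asl.append(np.nan)
    return (np.array(conc), np.array(kf), np.array(af),
            np.array(ks), np.array(asl))


def _plateau(conc, values, k_half) -> float:
    """Mean of a slow-phase quantity over concentrations > 2 * K_half."""
    mask = (conc > 2.0 * k_half) & np.isfinite(values)
    if not np.any(mask):
        mask = np.isfinite(values) & (conc >= np.median(conc))
    return float(np.mean(values[mask])) if np.any(mask) else float("nan")


def analyze_trp_titration(experiment: Experiment) -> dict:
    """Scheme-1 primaries from a tryptophan ATP titration.

    Returns k_plus2 (hyperbola plateau), one_over_K1 (half-saturation),
    K1k2 (initial slope), and k_slow (slow-phase plateau above 2x the
    half-saturating [ATP]).
    """
    records = _fit_traces(experiment.traces, "atp_um")
    conc, kf, af, ks, asl = _split_phases(records)
    series = an.KobsSeries("ATP", conc, kf, amplitude_pct=af, phase="fast")
    hyp = an.fit_hyperbola(series)
    k_slow = _plateau(conc, ks, hyp.k_half)
    return {
        "k_plus2": hyp.k_max, "se_k_plus2": hyp.se_k_max,
        "one_over_K1": hyp.k_half, "se_one_over_K1": hyp.se_k_half,
        "K1k2": hyp.initial_slope, "se_K1k2": hyp.se_initial_slope,
        "k_slow": k_slow,
        "detached_lifetime_ms": (1000.0 / k_slow if k_slow and
                                 np.isfinite(k_slow) else np.nan),
        "a_fast_pct": _plateau(conc, af, hyp.k_half),
        "series": series, "records": records,
    }


def analyze_pyrene_dissociation(experiment: Experiment) -> dict:
    """Scheme-2 primaries from ATP-induced acto·S1 dissociation."""
    records = _fit_traces(experiment.traces, "atp_um")
    conc, kf, af, ks, asl = _split_phases(records)
    series = an.KobsSeries("ATP", conc, kf, amplitude_pct=af, phase="fast")
    hyp = an.fit_hyperbola(series)
    k_plus_alpha = _plateau(conc, ks, hyp.k_half)
    a_fast = _plateau(conc, af, hyp.k_half)
    a_slow = _plateau(conc, asl, hyp.k_half)
    if np.isfinite(a_fast) and np.isfinite(a_slow) and a_slow > 0 \
            and np.isfinite(k_plus_alpha):
        K_alpha, k_minus_alpha = an.k_minus_alpha_from_amplitudes(
            a_fast, a_slow, k_plus_alpha)
    else:
        K_alpha, k_minus_alpha = np.nan, np.nan
    return {
        "k_plus2_prime": hyp.k_max, "se_k_plus2_prime": hyp.se_k_max,
        "one_over_K1_prime": hyp.k_half, "se_one_over_K1_prime": hyp.se_k_half,
        "K1k2_prime": hyp.initial_slope, "se_K1k2_prime": hyp.se_initial_slope,
        "k_plus_alpha": k_plus_alpha,
        "K_alpha": K_alpha, "k_minus_alpha": k_minus_alpha,
        "series": series, "records": records,
    }


def analyze_adp_competition(experiment: Experiment) -> dict:
    """Apparent ADP affinity of acto·S1 from the competition design."""
    records = _fit_traces(experiment.traces, "adp_um", n_phases=1)
    conc = np.array([r.conc_um for r in records])
    kobs = np.array([r.fit.phases[0].kobs for r in records])
    order = np.argsort(conc)
    series = an.KobsSeries("ADP", conc[order], kobs[order], phase="fast")
    atp = float(experiment.traces[0].meta.get("atp_um", np.nan))
    fit = an.fit_adp_competition(series, atp_conc_um=atp)
    return {"K_AD": fit.K_AD, "se_K_AD": fit.se_K_AD, "kobs0": fit.k0,
            "series": series, "records": records}


def analyze_adp_displacement(experiment: Experiment) -> dict:
    """ADP release rate and ADP-bound conformer constants.

    The fast (dominant) phase of the displacement record reports
    k_minusAD, the slow phase k_plus_alphaD, and their amplitude ratio
    estimates K_alphaD.
    """
    records = _fit_traces(experiment.traces, "adp_um", n_phases=2)
    fit = records[0].fit
    dom = fit.dominant_phase
    others = [p for p in fit.phases if p is not dom]
    out = {"k_minusAD": dom.kobs, "se_k_minusAD": dom.se_kobs,
           "records": records}
    if others:
        out["k_plus_alphaD"] = others[0].kobs
        if others[0].amplitude_pct > 0:
            out["K_alphaD"] = dom.amplitude_pct / others[0].amplitude_pct
    return out


def analyze_actin_titration(experiment: Experiment) -> dict:
    """Actin affinity (K_A or K_DA with ADP) from amplitude titration."""
    records = _fit_traces(experiment.traces, "s1_tot_nm", n_phases=1)
    conc = np.array([r.conc_um for r in records])
    amp = np.array([abs(r.fit.phases[0].amplitude_pct) for r in records])
    order = np.argsort(conc)
    a0 = float(experiment.traces[0].meta["actin_nm"])
    with_adp = bool(experiment.truth.get("with_adp",
                                         experiment.design.with_adp))
    curve = an.TitrationCurve(conc[order], amp[order], a0_nm=a0,
                              with_adp=with_adp)
    fit = an.fit_quadratic_titration(curve)
    key = "K_DA" if with_adp else "K_A"
    return {key: fit.K_D, f"se_{key}": fit.se_K_D,
            "tight_binding": fit.tight_binding,
            "curve": curve, "records": records}


_ANALYZERS = {
    "trp_atp_titration": analyze_trp_titration,
    "pyrene_atp_dissociation": analyze_pyrene_dissociation,
    "adp_competition": analyze_adp_competition,
    "adp_displacement": analyze_adp_displacement,
    "actin_titration": analyze_actin_titration,
    "actin_titration_adp": analyze_actin_titration,
}

#: parameters collected into the comparison report, with display names
#: (ASCII transliteration: k+2 -> k_plus2, K'1 -> K1_prime, α -> alpha)
#: and the design each is measured by.
REPORT_ROWS = [
    ("K1k2_prime", "K'1k'+2 (uM^-1 s^-1)", "pyrene_atp_dissociation"),
    ("k_plus2_prime", "k'+2 (s^-1)", "pyrene_atp_dissociation"),
    ("one_over_K1_prime", "1/K'1 (uM)", "pyrene_atp_dissociation"),
    ("k_plus_alpha", "k+alpha (s^-1)", "pyrene_atp_dissociation"),
    ("K_alpha", "K_alpha", "pyrene_atp_dissociation"),
    ("K_AD", "K_AD (uM)", "adp_competition"),
    ("k_minusAD", "k-AD (s^-1)", "adp_displacement"),
    ("k_plus_alphaD", "k+alphaD (s^-1)", "adp_displacement"),
    ("K_alphaD", "K_alphaD", "adp_displacement"),
    ("K_A", "K_A (nM)", "actin_titration"),
    ("K_DA", "K_DA (nM)", "actin_titration_adp"),
    ("K_DA_over_K_A", "K_DA/K_A", "actin_titration"),
    ("K1k2", "K1k+2 (uM^-1 s^-1)", "trp_atp_titration"),
    ("k_plus2", "k+2 (s^-1)", "trp_atp_titration"),
    ("one_over_K1", "1/K1 (uM)", "trp_atp_titration"),
    ("k_slow", "k+3+k-3 (s^-1)", "trp_atp_titration"),
    ("detached_lifetime_ms", "detached lifetime (ms)", "trp_atp_titration"),
]


def analyze_preparation(experiments: dict[str, Experiment]) -> dict:
    """Run every per-design analysis for one preparation.

    Returns a flat dict of parameter estimates (non-numeric bookkeeping
    such as series objects is kept under ``"_details"``).
    """
    out: dict = {}
    details: dict = {}
    for key, experiment in experiments.items():
        analyzer = _ANALYZERS.get(key)
        if analyzer is None:
            raise PipelineError(f"no analyzer for design {key!r}")
        res = analyzer(experiment)
        details[key] = res
        for name, value in res.items():
            if isinstance(value, (int, float, np.floating)) \
                    and not name.startswith("se_"):
                out[name] = float(value)
    if out.get("K_A") and out.get("K_DA"):
        out["K_DA_over_K_A"] = out["K_DA"] / out["K_A"]
    out["_details"] = details
    return out


# ---------------------------------------------------------------------
# Battery runner
# ---------------------------------------------------------------------

class BatteryConfig(BaseModel):
    """Configuration of a full synthetic-study run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 42
    n_preps: int = 3
    cv_scale: float = 1.0
    noise_sd_pct: float = 0.5
    out_dir: Optional[str] = None
    write_traces: bool = False
    params_wt_s1: str = "S1_WT"
    params_wt_acto: str = "ACTO_S1_WT"
    params_mut_s1: str = "S1_R453C"
    params_mut_acto: str = "ACTO_S1_R453C"
    designs: Optional[list[str]] = None

    def resolve(self, name: str) -> AnyParams:
        value = getattr(self, name)
        if value.upper() in PRESETS:
            return get_preset(value)
        return load_params(value)


@dataclass
class BatteryReport:
    """Summary-table-style comparison report plus per-prep parameter tables."""

    report: pd.DataFrame
    prep_tables: dict[str, pd.DataFrame]
    battery: Battery
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def to_json(self) -> str:
        return json.dumps({
            "report": json.loads(self.report.to_json(orient="index")),
            "preparations": {k: json.loads(v.to_json(orient="index"))
                             for k, v in self.prep_tables.items()},
            "failures": self.failures,
        }, indent=2, default=float)


def run_battery(config: BatteryConfig) -> BatteryReport:
    """Generate, fit and summarise the complete synthetic study."""
    instrument = InstrumentModel(noise_sd_pct=config.noise_sd_pct)
    all_designs = default_designs()
    if config.designs:
        all_designs = [d for d in all_designs if d.kind in config.designs]
        if not all_designs:
            raise PipelineError(f"no valid designs in {config.designs}")
    logger.info("generating battery: seed=%d, %d preps, noise %.2g%%",
                config.seed, config.n_preps, config.noise_sd_pct)
    bat = battery(
        config.resolve("params_wt_s1"), config.resolve("params_wt_acto"),
        config.resolve("params_mut_s1"), config.resolve("params_mut_acto"),
        seed=config.seed, n_preps=config.n_preps, cv_scale=config.cv_scale,
        instrument=instrument, designs=all_designs)

    failures: list[str] = []
    prep_tables: dict[str, pd.DataFrame] = {}
    details_store: dict[str, list[dict]] = {}
    for construct, preps in bat.preparations.items():
        rows = []
        details_store[construct] = []
        for prep in preps:
            try:
                est = analyze_preparation(prep.experiments)
            except Exception as exc:  # partial failure -> gap + record
                logger.error("analysis failed for %s prep %d: %s",
                             construct, prep.index, exc)
                failures.append(f"{construct}/prep{prep.index}: {exc}")
                est = {}
            details_store[construct].append(est.pop("_details", {}))
            rows.append({k: v for k, v in est.items()
                         if isinstance(v, float)})
        prep_tables[construct] = pd.DataFrame(rows)

    keys = [k for k, _, _ in REPORT_ROWS]
    wt = prep_tables.get("WT", pd.DataFrame())
    mut = prep_tables.get("R453C", pd.DataFrame())
    wt = wt.reindex(columns=[k for k in keys if k in wt.columns])
    mut = mut.reindex(columns=[k for k in keys if k in mut.columns])
    report = an.compare_constructs(wt, mut)
    display = {k: d for k, d, _ in REPORT_ROWS}
    provenance = {k: p for k, _, p in REPORT_ROWS}
    report.insert(0, "name", [display.get(k, k) for k in report.index])
    report["measured_by"] = [provenance.get(k, "") for k in report.index]

    result = BatteryReport(report=report, prep_tables=prep_tables,
                           battery=bat, failures=failures)
    if config.out_dir:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: BatteryReport, config: BatteryConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out / "report.tsv", sep="\t")
    (out / "report.json").write_text(result.to_json() + "\n")
    (out / "truth_manifest.json").write_text(
        json.dumps(result.battery.truth_manifest(), indent=2,
                   default=float) + "\n")
    for construct, preps in result.battery.preparations.items():
        for prep in preps:
            pdir = out / construct / f"prep{prep.index}"
            pdir.mkdir(parents=True, exist_ok=True)
            if config.write_traces:
                for key, experiment in prep.experiments.items():
                    for i, tr in enumerate(experiment.traces):
                        write_trace(tr, pdir / f"{key}_{i:02d}.tsv")
    for construct, table in result.prep_tables.items():
        table.to_csv(out / f"preps_{construct}.tsv", sep="\t",
                     index_label="prep")
    logger.info("artifacts written to %s", out)


# ---------------------------------------------------------------------
# Single-file fitting entry point
# ---------------------------------------------------------------------

def fit_file(path: Union[str, Path], n_phases: Union[int, str] = "auto",
             plot: Optional[Union[str, Path]] = None) -> ExpFitResult:
    """Fit a trace file and return the exponential-fit record.

    With ``plot`` set, writes a data + fit + residual figure.
    """
    trace = read_trace(path)
    fitter = ExponentialTransientFitter(n_phases=n_phases).fit(trace)
    result = fitter.result_
    if plot is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax0, ax1) = plt.subplots(
            2, 1, sharex=True, figsize=(6, 5),
            gridspec_kw={"height_ratios": [3, 1]})
        pred = fitter.predict(trace.time)
        ax0.plot(trace.time, trace.signal, ".", ms=2, label="data")
        ax0.plot(trace.time, pred, "-", label=f"{result.n_phases}-exp fit")
        ax0.set_ylabel("rel. fluorescence")
        ax0.legend()
        ax1.plot(trace.time, trace.signal - pred, ".", ms=2)
        ax1.axhline(0, color="k", lw=0.5)
        ax1.set_xlabel("time (s)")
        ax1.set_ylabel("residual")
        ax0.set_xscale("log")
        ax1.set_xscale("log")
        fig.tight_layout()
        fig.savefig(plot, dpi=120)
        plt.close(fig)
    return result
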