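"""Fluorescence transients and per-state observable yields.

A stopped-flow record is a time series of relative fluorescence,
normalised so that the pre-mix level is 1.  Traces are exchanged as
two-column delimited text with a ``#`` header block carrying JSON
metadata, e.g.::

    # myokin-trace v1
    # meta: {"probe": "tryptophan", "atp_um": 250.0, "seed": 7}
    # columns: time_s	rel_fluorescence
    0.001500	1.000312
    ...
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

__all__ = [
    "FluorescenceTrace",
    "ObservableMap",
    "trp_observables",
    "pyrene_observables",
    "read_trace",
    "write_trace",
    "TraceFormatError",
]

MIN_SAMPLES = 50


class TraceFormatError(ValueError):
    """Raised when a trace file does not parse."""


@dataclass
class FluorescenceTrace:
    """Time series of relative fluorescence with experiment metadata.

    Parameters
    ----------
    time : ndarray
        Seconds, strictly increasing; the first point is at (or after)
        the instrument dead time.
    signal : ndarray
        Relative fluorescence, dimensionless (pre-mix level = 1).
    meta : dict
        Probe kind, post-mix concentrations (μM), temperature tag, seed
        and (for synthetic traces) the generating truth.
    """

    time: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise ValueError("time and signal must be 1-d arrays of equal length")
        if self.time.size < MIN_SAMPLES:
            raise ValueError(f">= {MIN_SAMPLES} samples required, got {self.time.size}")
        if np.any(~np.isfinite(self.time)) or np.any(~np.isfinite(self.signal)):
            raise ValueError("trace contains NaN or infinite values")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.time[0] < 0:
            raise ValueError("time must be non-negative")

    def __len__(self) -> int:
        return self.time.size

    @property
    def premix_level(self) -> float:
        """Pre-mix fluorescence level; amplitudes are quoted as % of this."""
        return float(self.meta.get("premix_level", 1.0))


@dataclass(frozen=True)
class ObservableMap:
    """Relative fluorescence yield of each scheme state.

    Yields are a signal calibration, not physics: the source study reports
    only phase amplitudes, so the defaults are chosen to reproduce the
    printed amplitude structure (see :func:`trp_observables` and
    :func:`pyrene_observables`).
    """

    yields: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = list(self.yields.values())
        if any(v < 0 for v in vals):
            raise ValueError("fluorescence yields must be >= 0")
        if len(set(np.round(vals, 12))) < 2:
            raise ValueError("at least two distinct yields required (no signal)")

    def vector(self, states: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.yields[s] for s in states], dtype=float)
        except KeyError as exc:
            raise KeyError(f"no yield defined for state {exc.args[0]!r}") from exc


def trp_observables(fast_amplitude: float = 0.17,
                    slow_amplitude: float = 0.01) -> ObservableMap:
    """Tryptophan yields for Scheme 1.

    The isomerisation step (M·T → M*·T) carries ``fast_amplitude`` of the
    pre-mix level and the hydrolysis step a further ``slow_amplitude``
    (defaults 17% / 1%, the printed amplitudes for the mutant construct).
    Product release does not change the signal, so the lumped exit state
    shares the post-hydrolysis yield.
    """
    return ObservableMap({
        "M": 1.0,
        "M.T": 1.0,
        "M~M.T": 1.0,
        "M*.T": 1.0 + fast_amplitude,
        "M**.D.Pi": 1.0 + fast_amplitude + slow_amplitude,
        "products": 1.0 + fast_amplitude + slow_amplitude,
    })


def pyrene_observables(total_change: float = 0.34) -> ObservableMap:
    """Pyrene-actin yields for Scheme 2.

    Pyrene fluorescence is quenched in the actin·S1 complex; all bound
    states share the (normalised) pre-mix yield 1 and free pyrene-actin is
    brighter by ``total_change`` (default 34%, matching the printed fast +
    slow amplitudes of the ATP-induced dissociation).
    """
    return ObservableMap({
        "A.M'": 1.0,
        "A.M": 1.0,
        "A.M.D": 1.0,
        "A.M'.D": 1.0,
        "A~M.D": 1.0,
        "A+M": 1.0 + total_change,
    })


_TRUTH_KEYS = ("truth",)


def write_trace(trace: FluorescenceTrace, path: Union[str, Path],
                strip_truth: bool = True) -> None:
    """Write a trace in the two-column text format.

    ``strip_truth`` removes the generating-truth record from the metadata
    (synthetic traces carry it for recovery scoring only).
    """
    meta = {k: v for k, v in trace.meta.items()
            if not (strip_truth and k in _TRUTH_KEYS)}
    lines = [
        "# myokin-trace v1",
        "# meta: " + json.dumps(meta, default=float),
        "# columns: time_s\trel_fluorescence",
    ]
    lines += [f"{t:.6e}\t{s:.8e}" for t, s in zip(trace.time, trace.signal)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path: Union[str, Path]) -> FluorescenceTrace:
    """Read a trace written by :func:`write_trace`.

    Raises
    ------
    TraceFormatError
        Naming the offending line on malformed input.
    """
    path = Path(path)
    meta: dict = {}
    times: list[float] = []
    signals: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("meta:"):
                try:
                    meta = json.loads(body[len("meta:"):])
                except json.JSONDecodeError as exc:
                    raise TraceFormatError(
                        f"{path}:{lineno}: malformed metadata JSON"
                    ) from exc
            continue
        parts = line.split()
        if len(parts) != 2:
            raise TraceFormatError(
                f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
            )
        try:
            times.append(float(parts[0]))
            signals.append(float(parts[1]))
        except ValueError as exc:
            raise TraceFormatError(
                f"{path}:{lineno}: non-numeric value {line!r}"
            ) from exc
    if len(times) < MIN_SAMPLES:
        raise TraceFormatError(
            f"{path}: >= {MIN_SAMPLES} samples required, got {len(times)}"
        )
    try:
        return FluorescenceTrace(np.array(times), np.array(signals), meta)
    except ValueError as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc
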