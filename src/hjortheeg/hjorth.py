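"""Hjorth parameters: Activity, Mobility and Complexity of a sampled signal.

The three Hjorth parameters are time-domain descriptors of a signal ``x``:

* **Activity** — the variance of the signal, a direct measure of its power
  (in µV² for EEG).
* **Mobility** — ``sqrt(Var(d) / Var(x))`` where ``d`` is the first
  difference ``d_i = x_{i+1} - x_i``.  It is a dimensionless per-sample
  rate that acts as a mean-frequency proxy: a sampled sinusoid at
  frequency ``f`` has mobility ``2·sin(π·f/fs)``.
* **Complexity** — the mobility of the first difference divided by the
  mobility of the signal, a bandwidth / waveform-irregularity proxy.
  It equals 1 for a pure sinusoid and exceeds 1 for any broader spectrum
  (a Cauchy–Schwarz inequality on the spectral moments).

All variances here use the population denominator (mean of squared
deviations over the entries actually present).  This keeps Activity
exactly quadratic under scaling and makes Mobility/Complexity exactly
scale invariant; the alternative ``1/(N-1)`` convention differs by an
O(1/N) factor that is irrelevant at EEG trial lengths.

Degenerate signals (zero variance, so Mobility is undefined) raise
:class:`DegenerateSignalError` from the scalar functions.  The bundled
:func:`hjorth_triple` and :func:`windowed_hjorth` support a non-strict
bulk mode that substitutes NaN and logs a warning instead, so one flat
channel cannot abort a dataset run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .io import Trial

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateSignalError",
    "HjorthTriple",
    "HjorthSeries",
    "activity",
    "first_difference",
    "mobility",
    "complexity",
    "hjorth_triple",
    "windowed_hjorth",
]


class DegenerateSignalError(ValueError):
    """Raised when a Hjorth parameter is undefined (zero-variance input)."""


def _as_signal(x, min_length: int) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D signal vector, got shape {arr.shape}")
    if arr.size < min_length:
        raise ValueError(f"signal must have at least {min_length} samples, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("signal contains non-finite values")
    return arr


def activity(x) -> float:
    """Variance (power) of the signal, population denominator.

    For a signal in microvolts the result is in µV².
    """
    arr = _as_signal(x, 2)
    return float(arr.var())


def first_difference(x) -> np.ndarray:
    """Consecutive differences ``d_i = x_{i+1} - x_i`` (length ``len(x) - 1``)."""
    arr = _as_signal(x, 2)
    return np.diff(arr)


def mobility(x) -> float:
    """``sqrt(Var(d) / Var(x))`` — dimensionless per-sample rate in [0, 2]."""
    arr = _as_signal(x, 3)
    var_x = float(arr.var())
    if var_x <= 0.0:
        raise DegenerateSignalError("mobility undefined: signal has zero variance")
    var_d = float(np.diff(arr).var())
    return math.sqrt(var_d / var_x)


def complexity(x) -> float:
    """Mobility of the first difference divided by mobility of the signal."""
    arr = _as_signal(x, 4)
    d = np.diff(arr)
    if float(arr.var()) <= 0.0:
        raise DegenerateSignalError("complexity undefined: signal has zero variance")
    if float(d.var()) <= 0.0:
        raise DegenerateSignalError(
            "complexity undefined: first difference has zero variance"
        )
    return mobility(d) / mobility(arr)


@dataclass(frozen=True)
class HjorthTriple:
    """Activity (µV²), mobility and complexity (dimensionless) of one signal."""

    activity: float
    mobility: float
    complexity: float

    def astuple(self) -> tuple[float, float, float]:
        return (self.activity, self.mobility, self.complexity)


def hjorth_triple(x, strict: bool = True) -> HjorthTriple:
    """All three Hjorth parameters of one signal vector.

    Parameters
    ----------
    x : array-like
        Signal vector, length >= 4, finite values.
    strict : bool
        If True (the scalar-call default) degenerate signals raise
        :class:`DegenerateSignalError`.  If False (bulk mode) the
        undefined entries are returned as NaN — activity is still 0 for
        a constant signal — and a warning is logged.
    """
    arr = _as_signal(x, 4)
    act = float(arr.var())
    try:
        mob = mobility(arr)
        comp = complexity(arr)
    except DegenerateSignalError:
        if strict:
            raise
        logger.warning("degenerate signal in bulk mode: mobility/complexity set to NaN")
        mob = mobility(arr) if act > 0 else math.nan
        comp = math.nan
    return HjorthTriple(act, mob, comp)


@dataclass(frozen=True)
class HjorthSeries:
    """Windowed Hjorth parameters of a multichannel trial.

    ``windows`` maps electrode number (1-based) to an ordered list of
    ``(window_start_sample, HjorthTriple)``; starts increase by ``hop``
    and every window lies fully inside the trial.
    """

    windows: dict[int, list[tuple[int, HjorthTriple]]]
    window_length: int
    hop: int

    @property
    def n_windows(self) -> int:
        return len(next(iter(self.windows.values()))) if self.windows else 0


def windowed_hjorth(
    trial: "Trial", window_length: int, hop: int, strict: bool = False
) -> HjorthSeries:
    """Hjorth triples over sliding windows, per electrode.

    Windows start at 0, hop, 2·hop, …; a trailing partial window is
    discarded.  ``window_length`` must satisfy
    ``4 <= window_length <= n_samples`` and ``hop >= 1``.
    """
    n_samples = trial.n_samples
    if window_length < 4:
        raise ValueError("window_length must be at least 4 samples")
    if window_length > n_samples:
        raise ValueError(
            f"window_length {window_length} exceeds trial length {n_samples}"
        )
    if hop < 1:
        raise ValueError("hop must be at least 1 sample")

    starts = range(0, n_samples - window_length + 1, hop)
    windows: dict[int, list[tuple[int, HjorthTriple]]] = {}
    for electrode, channel in zip(trial.electrodes, trial.data):
        windows[electrode] = [
            (start, hjorth_triple(channel[start : start + window_length], strict=strict))
            for start in starts
        ]
    return HjorthSeries(windows=windows, window_length=window_length, hop=hop)
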