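"""Sensor calibration: Ca2+-selective microelectrodes and ACh-sensor dF/F.

Ca2+-selective microelectrodes follow a Nernstian response: the measured
potential varies linearly with log10 of the Ca2+ concentration.  The
calibration curve V = slope * log10([Ca2+]) + intercept is fitted by least
squares to points at known concentrations; the electrode's sensitivity is
the potential jump over the 0.2 -> 2 mM decade (equal to the fitted slope),
and only electrodes with sensitivity above 20 mV are accepted.

Fluorescent ACh-sensor (GRAB-type) recordings are expressed as
dF/F = (F_t - F_0) / F_0, where F_t is the background-subtracted intensity
and F_0 its mean over the 1 s window before stimulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationCurve",
    "FluorescenceSeries",
    "SENSITIVITY_GATE_MV",
    "fit_ca_calibration",
    "voltage_to_concentration",
    "compute_dff",
]

SENSITIVITY_GATE_MV = 20.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted log-linear electrode calibration.

    ``points`` holds the raw (conc_mM, potential_mV) pairs including any
    0 mM reading; only positive concentrations enter the fit.
    """

    points: tuple[tuple[float, float], ...]
    slope: float  # mV per decade
    intercept: float  # mV at 1 mM
    sensitivity: float  # predicted jump from 0.2 to 2 mM, mV
    accepted: bool


@dataclass(frozen=True)
class FluorescenceSeries:
    """A fluorescence recording with its background ROI series.

    ``signal`` and ``background`` are raw intensities per frame; the
    background comes from an equal-sized ROI without sensor expression.
    """

    frame_rate: float = 10.0
    signal: np.ndarray = None
    background: np.ndarray = None
    f0_window_s: float = 1.0

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, float)
        bg = np.asarray(self.background, float)
        if sig.shape != bg.shape:
            raise ValueError("signal and background must have equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if int(round(self.f0_window_s * self.frame_rate)) < 1:
            raise ValueError("baseline window must span at least one frame")
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "background", bg)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.signal.size) / self.frame_rate


def fit_ca_calibration(points) -> CalibrationCurve:
    """Least-squares log-linear fit to electrode calibration points.

    ``points`` is an iterable of (conc_mM, potential_mV).  The 0 mM point
    (log undefined) is retained in ``points`` but excluded from the fit.
    Sensitivity is the fitted potential difference between 2 and 0.2 mM —
    one decade, hence the slope itself — and the electrode is accepted only
    when it exceeds 20 mV.
    """
    pts = [(float(c), float(v)) for c, v in np.asarray(points, float)]
    pos = [(c, v) for c, v in pts if c > 0]
    if len(pos) < 2:
        raise ValueError("need at least 2 points with positive concentration")
    logc = np.log10([c for c, _ in pos])
    pot = np.array([v for _, v in pos])
    slope, intercept = np.polyfit(logc, pot, 1)
    sensitivity = float(slope)  # V(2 mM) - V(0.2 mM) = slope * 1 decade
    return CalibrationCurve(
        points=tuple(pts), slope=float(slope), intercept=float(intercept),
        sensitivity=sensitivity,
        accepted=sensitivity > SENSITIVITY_GATE_MV)


def predict_potential(curve: CalibrationCurve, conc_mm: float) -> float:
    """Forward model: potential (mV) at a given concentration (mM)."""
    if conc_mm <= 0:
        raise ValueError("concentration must be positive")
    return curve.slope * math.log10(conc_mm) + curve.intercept


def voltage_to_concentration(curve: CalibrationCurve,
                             potential_mv: float) -> float:
    """Invert an accepted calibration: [Ca2+] = 10**((V - b) / slope), mM."""
    if not curve.accepted:
        raise ValueError("calibration curve failed the sensitivity gate")
    return 10.0 ** ((potential_mv - curve.intercept) / curve.slope)


def compute_dff(series: FluorescenceSeries, stim_onset_s: float) -> np.ndarray:
    """Background-subtracted dF/F relative to the pre-stimulus baseline.

    F_t = signal - background per frame; F_0 is the mean F_t over the
    ``f0_window_s`` before ``stim_onset_s``.  Raises on a non-positive
    baseline (no sensor signal above background).
    """
    n0 = int(round(series.f0_window_s * series.frame_rate))
    i_on = int(round(stim_onset_s * series.frame_rate))
    if i_on < n0:
        raise ValueError("need the full baseline window before stimulation")
    f_t = series.signal - series.background
    f0 = f_t[i_on - n0:i_on].mean()
    if f0 <= 0:
        raise ValueError(f"degenerate baseline: F0 = {f0:.3g}")
    return (f_t - f0) / f0
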