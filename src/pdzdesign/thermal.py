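"""Differential scanning fluorimetry: T1/2 extraction and thermal shifts.

The melting midpoint is obtained by least-squares fitting of a Boltzmann
sigmoid f(T) = f_min + (f_max - f_min) / (1 + exp((T1/2 - T)/s)).  A ligand
is called bound when the holo-apo midpoint shift exceeds the sum of the two
standard deviations over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, InvalidConfigError, PdzDesignError

__all__ = [
    "MeltCurve",
    "ThermalShiftResult",
    "boltzmann_sigmoid",
    "fit_melt",
    "fit_t_half",
    "thermal_shift",
    "thermal_shift_from_stats",
    "read_melt_csv",
    "write_melt_csv",
]


@dataclass(frozen=True)
class MeltCurve:
    """One DSF melt curve: temperature grid (deg C) and fluorescence (AU)."""

    temperatures: np.ndarray
    fluorescence: np.ndarray
    replicate_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if len(t) != len(f):
            raise InvalidConfigError("temperature/fluorescence length mismatch")
        if np.any(np.diff(t) <= 0):
            raise InvalidConfigError("temperature grid must strictly increase")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)


def write_melt_csv(curve: MeltCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "temperature_C": curve.temperatures,
            "fluorescence": curve.fluorescence,
        }
    ).to_csv(path, index=False)


def read_melt_csv(path: str | Path, replicate_id: str = "") -> MeltCurve:
    df = pd.read_csv(path)
    return MeltCurve(
        temperatures=df["temperature_C"].to_numpy(),
        fluorescence=df["fluorescence"].to_numpy(),
        replicate_id=replicate_id,
    )


def boltzmann_sigmoid(t, f_min, f_max, t_half, slope):
    return f_min + (f_max - f_min) / (1.0 + np.exp((t_half - t) / slope))


def fit_melt(curve: MeltCurve) -> dict:
    """Fit the Boltzmann sigmoid; returns all four parameters.

    Initialization: baseline/plateau from the data range, midpoint at the
    steepest grid point (max |df/dT|), unit slope.
    """
    t, f = curve.temperatures, curve.fluorescence
    if len(t) < 6:
        raise PdzDesignError("need at least 6 points spanning the transition")
    grad = np.gradient(f, t)
    k = int(np.argmax(np.abs(grad)))
    p0 = [float(f.min()), float(f.max()), float(t[k]),
          1.0 if grad[k] >= 0 else -1.0]
    try:
        popt, pcov = curve_fit(
            boltzmann_sigmoid, t, f, p0=p0, maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(
            "melt-curve fit did not converge",
            diagnostics={"p0": p0, "n_points": len(t),
                         "replicate": curve.replicate_id},
        ) from exc
    if not np.all(np.isfinite(popt)):
        raise FitError(
            "melt-curve fit produced non-finite parameters",
            diagnostics={"popt": popt.tolist()},
        )
    return {
        "f_min": float(popt[0]),
        "f_max": float(popt[1]),
        "t_half": float(popt[2]),
        "slope": float(popt[3]),
        "cov": pcov,
    }


def fit_t_half(curve: MeltCurve) -> float:
    """Melting midpoint T1/2 in deg C."""
    return fit_melt(curve)["t_half"]


@dataclass(frozen=True)
class ThermalShiftResult:
    """Apo/holo midpoints, their spreads, and the binding call."""

    t_half_apo: float
    t_half_holo: float
    sd_apo: float
    sd_holo: float
    delta: float
    significant: bool

    def __post_init__(self):
        if abs(self.delta - (self.t_half_holo - self.t_half_apo)) > 1e-9:
            raise PdzDesignError("delta must equal holo - apo")


def thermal_shift_from_stats(
    t_apo: float, sd_apo: float, t_holo: float, sd_holo: float
) -> ThermalShiftResult:
    """Binding call from replicate means and standard deviations.

    delta = holo - apo (positive = stabilization); significant iff
    delta > sd_apo + sd_holo.
    """
    delta = t_holo - t_apo
    return ThermalShiftResult(
        t_half_apo=t_apo,
        t_half_holo=t_holo,
        sd_apo=sd_apo,
        sd_holo=sd_holo,
        delta=delta,
        significant=delta > sd_apo + sd_holo,
    )


def _stats(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def thermal_shift(
    apo: list[MeltCurve] | list[float],
    holo: list[MeltCurve] | list[float],
) -> ThermalShiftResult:
    """Thermal shift over replicates.

    Accepts either melt curves (fitted here) or already-extracted T1/2
    values.  Standard deviations are sample (n-1) estimates; 0 for single
    replicates.
    """
    if not apo or not holo:
        raise PdzDesignError("need at least one replicate per condition")

    def extract(items):
        return [
            fit_t_half(x) if isinstance(x, MeltCurve) else float(x)
            for x in items
        ]

    t_apo, sd_apo = _stats(extract(apo))
    t_holo, sd_holo = _stats(extract(holo))
    return thermal_shift_from_stats(t_apo, sd_apo, t_holo, sd_holo)
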