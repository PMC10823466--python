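"""Magnetic-tweezer rotation-extension analysis.

A torsionally relaxed tether under low force traces an approximately Gaussian
extension-vs-turns curve; its maximum locates the relaxed state.  The pipeline
averages repeated sweeps, fits ``baseline + A*exp(-(n-c)^2/(2w^2))`` by
nonlinear least squares, tracks the fitted peak center across temperature
(re-zeroed at a reference temperature), and converts the pooled center-change
slope into a twist-temperature slope in degrees/(C*kbp) with the 2 x SD error
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy import stats

from .trajectory_analysis import SlopeFit

__all__ = [
    "RotExtCurve",
    "GaussianPeak",
    "PeakFitError",
    "average_curves",
    "decimate_curve",
    "fit_gaussian_peak",
    "center_shift_to_twist",
    "twist_temperature_regression",
    "analyze_traces",
]


@dataclass
class RotExtCurve:
    """One extension-vs-turns trace."""

    turns: np.ndarray
    extension: np.ndarray       # um
    temperature: float | None = None  # Celsius
    tether_id: str = "t0"
    tether_length_kbp: float = 3.3
    n_replicates: int = 1
    replicate: int = 0

    def __post_init__(self) -> None:
        self.turns = np.asarray(self.turns, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.turns.shape != self.extension.shape:
            raise ValueError("turns and extension must have the same length")


@dataclass
class GaussianPeak:
    """Fitted Gaussian peak of a rotation-extension curve."""

    center: float       # turns
    width: float        # turns (Gaussian sigma)
    amplitude: float    # um
    baseline: float     # um
    center_sd: float    # turns, from the fit covariance


class PeakFitError(RuntimeError):
    pass


def average_curves(curves: list[RotExtCurve]) -> RotExtCurve:
    """Pointwise mean of repeated sweeps sharing a turns grid."""
    if not curves:
        raise ValueError("no curves to average")
    ref = curves[0]
    for c in curves[1:]:
        if c.turns.shape != ref.turns.shape or not np.allclose(c.turns, ref.turns):
            raise ValueError("replicates must share the turns grid")
    ext = np.mean([c.extension for c in curves], axis=0)
    return RotExtCurve(
        turns=ref.turns.copy(),
        extension=ext,
        temperature=ref.temperature,
        tether_id=ref.tether_id,
        tether_length_kbp=ref.tether_length_kbp,
        n_replicates=len(curves),
    )


def decimate_curve(curve: RotExtCurve, factor: int = 10) -> RotExtCurve:
    """Keep every ``factor``-th point (display-style decimation)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return RotExtCurve(
        turns=curve.turns[::factor],
        extension=curve.extension[::factor],
        temperature=curve.temperature,
        tether_id=curve.tether_id,
        tether_length_kbp=curve.tether_length_kbp,
        n_replicates=curve.n_replicates,
    )


def _gaussian(n, baseline, amplitude, center, width):
    return baseline + amplitude * np.exp(-((n - center) ** 2) / (2.0 * width**2))


def fit_gaussian_peak(curve: RotExtCurve) -> GaussianPeak:
    """Least-squares Gaussian fit of one rotation-extension curve.

    Initialized from the argmax and the second moment of the
    baseline-subtracted extension; the center uncertainty comes from the fit
    covariance.
    """
    n = curve.turns
    z = curve.extension
    if n.size < 5:
        raise ValueError("need >= 5 points spanning the peak")
    b0 = float(z.min())
    a0 = float(z.max() - z.min())
    c0 = float(n[np.argmax(z)])
    w = z - b0
    wsum = w.sum()
    if a0 <= 0 or wsum <= 0:
        raise PeakFitError("curve has no peak above its baseline")
    var0 = float(np.sum(w * (n - c0) ** 2) / wsum)
    w0 = max(np.sqrt(var0), np.ptp(n) / 50.0)
    p0 = (b0, a0, c0, w0)
    try:
        popt, pcov = curve_fit(_gaussian, n, z, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise PeakFitError(
            f"Gaussian fit did not converge (init {p0}): {exc}"
        ) from exc
    baseline, amplitude, center, width = popt
    if width < 0:  # sign-degenerate parameterization
        width = -width
    center_sd = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
    return GaussianPeak(
        center=float(center),
        width=float(width),
        amplitude=float(amplitude),
        baseline=float(baseline),
        center_sd=center_sd,
    )


def center_shift_to_twist(
    delta_turns: float, delta_temperature: float, tether_length_kbp: float
) -> float:
    """Convert a peak-center shift into a twist slope, degrees/(C*kbp).

    One turn is 360 degrees of twist over the whole tether; the sign of the
    shift is preserved (unwinding with temperature is negative).
    """
    if delta_temperature == 0:
        raise ValueError("delta_temperature must be nonzero")
    if tether_length_kbp <= 0:
        raise ValueError("tether_length_kbp must be positive")
    return delta_turns * 360.0 / (delta_temperature * tether_length_kbp)


def twist_temperature_regression(
    peaks: pd.DataFrame,
    ref_temperature: float = 25.0,
    tether_length_kbp: float = 3.3,
) -> SlopeFit:
    """Pooled OLS of re-zeroed peak centers on temperature across tethers.

    ``peaks`` needs columns ``tether_id``, ``temperature_C``, ``center_turns``;
    each tether must include a measurement at ``ref_temperature``, whose center
    is subtracted (the value at the reference is set to zero).  The slope is
    returned in turns/C and converted to degrees/(C*kbp); the reported error is
    twice the slope standard deviation.
    """
    if peaks["temperature_C"].nunique() < 3:
        raise ValueError("need >= 3 temperatures")
    rows = []
    for tid, grp in peaks.groupby("tether_id"):
        at_ref = grp.loc[np.isclose(grp["temperature_C"], ref_temperature)]
        if at_ref.empty:
            raise ValueError(
                f"tether {tid}: no measurement at reference {ref_temperature} C"
            )
        zero = float(at_ref["center_turns"].iloc[0])
        g = grp.copy()
        g["center_change"] = g["center_turns"] - zero
        rows.append(g)
    pooled = pd.concat(rows, ignore_index=True)
    res = stats.linregress(pooled["temperature_C"], pooled["center_change"])
    scale = 360.0 / tether_length_kbp
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_sd=float(res.stderr),
        r_squared=float(res.rvalue**2),
        slope_per_kbp=float(res.slope * scale),
        slope_per_kbp_sd=float(res.stderr * scale),
        n_points=len(pooled),
    )


def analyze_traces(
    df: pd.DataFrame,
    ref_temperature: float = 25.0,
    tether_length_kbp: float = 3.3,
) -> tuple[pd.DataFrame, SlopeFit]:
    """Full tweezer pipeline on a tidy trace table.

    ``df`` needs columns ``turns``, ``extension_um``, ``temperature_C``,
    ``tether_id`` and optionally ``replicate``.  Replicate sweeps are averaged
    pointwise, each averaged curve is Gaussian-fitted, and the fitted centers
    are pooled into the temperature regression.  Returns (per-tether peak
    table, pooled slope fit).
    """
    if "replicate" not in df.columns:
        df = df.assign(replicate=0)
    records = []
    for (tid, temp), grp in df.groupby(["tether_id", "temperature_C"]):
        reps = [
            RotExtCurve(
                turns=g["turns"].to_numpy(),
                extension=g["extension_um"].to_numpy(),
                temperature=float(temp),
                tether_id=str(tid),
                tether_length_kbp=tether_length_kbp,
            )
            for _, g in grp.groupby("replicate")
        ]
        peak = fit_gaussian_peak(average_curves(reps))
        records.append(
            {
                "tether_id": str(tid),
                "temperature_C": float(temp),
                "center_turns": peak.center,
                "center_sd": peak.center_sd,
                "width_turns": peak.width,
                "amplitude_um": peak.amplitude,
                "baseline_um": peak.baseline,
            }
        )
    table = pd.DataFrame.from_records(records)
    fit = twist_temperature_regression(
        table, ref_temperature=ref_temperature, tether_length_kbp=tether_length_kbp
    )
    return table, fit
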