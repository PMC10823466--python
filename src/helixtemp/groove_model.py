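"""Quadratic twist-groove free-energy re-analysis.

The model assumes a free energy of the major-groove width G at absolute
temperature T of the form

    F(G, T) = U(G) - T * S(G),

with internal energy U and entropy S independent of temperature.  Fitting
F(G, T) at two temperatures by quadratics and subtracting yields S(G)
coefficientwise; the groove minimum G0(T) = argmin_G F(G, T) then shifts with
temperature at an analytically known rate, and an elastic twist-groove coupling
converts that shift into a twist change per degree:

    d_omega = -(k_omega_G / k_omega) * dG0/dT.

A quadratic S makes any straight-line fit to S(G) arbitrary (its slope depends
on the sampled window), so linear entropy fits are reported together with the
significance of the quadratic term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Quadratic",
    "LinearEntropyFit",
    "fit_quadratic",
    "entropy_between_temps",
    "quadratic_minimum",
    "groove_shift_rate",
    "twist_change_from_groove",
    "estimate_dG",
    "fit_linear_entropy",
]


@dataclass(frozen=True)
class Quadratic:
    """a*G^2 + b*G + c with unit bookkeeping left to the caller."""

    a: float
    b: float
    c: float
    residual_rms: float = 0.0

    def __call__(self, g):
        return self.a * np.asarray(g, dtype=float) ** 2 + self.b * np.asarray(
            g, dtype=float
        ) + self.c

    def coeffs(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


def fit_quadratic(g: np.ndarray, f: np.ndarray) -> Quadratic:
    """Least-squares quadratic through (G, F) samples; residual RMS recorded."""
    g = np.asarray(g, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.unique(g).size < 3:
        raise ValueError("need >= 3 distinct G values for a quadratic fit")
    coef = np.polyfit(g, f, 2)
    resid = f - np.polyval(coef, g)
    return Quadratic(
        float(coef[0]), float(coef[1]), float(coef[2]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def entropy_between_temps(
    f_t1: Quadratic, f_t2: Quadratic, t1: float, t2: float
) -> Quadratic:
    """S = (F_T1 - F_T2) / (T2 - T1), coefficientwise (temperatures in K)."""
    if t1 == t2:
        raise ValueError("temperatures must differ")
    d = t2 - t1
    return Quadratic(
        (f_t1.a - f_t2.a) / d, (f_t1.b - f_t2.b) / d, (f_t1.c - f_t2.c) / d
    )


def quadratic_minimum(q: Quadratic) -> float:
    """Location of the minimum, G0 = -b / (2a); requires convexity (a > 0)."""
    if q.a <= 0:
        raise ValueError(f"quadratic is not convex (a = {q.a})")
    return -q.b / (2.0 * q.a)


def groove_shift_rate(f_at_t0: Quadratic, s: Quadratic, t0: float) -> float:
    """Temperature derivative of the groove minimum, dG0/dT at T0.

    With F(G, T) = F(G, T0) - (T - T0) * S(G) and quadratic F and S, the
    minimum G0(T) = (-b_F + tau*b_S) / (2 (a_F - tau*a_S)) (tau = T - T0) has
    the analytic derivative (a_F * b_S - a_S * b_F) / (2 a_F^2) at tau = 0.
    """
    if f_at_t0.a <= 0:
        raise ValueError(f"free energy not convex at T0 (a = {f_at_t0.a})")
    for tau in (-1.0, 1.0):
        if f_at_t0.a - tau * s.a <= 0:
            warnings.warn(
                f"convexity lost within 1 K of T0 = {t0} (tau = {tau:+g})",
                stacklevel=2,
            )
    return (f_at_t0.a * s.b - s.a * f_at_t0.b) / (2.0 * f_at_t0.a**2)


def twist_change_from_groove(
    k_omega: float, k_omega_g: float, d_g: float
) -> float:
    """Coupled twist change per degree: d_omega = -(k_omega_G / k_omega) * dG.

    Minimizing the elastic energy (1/2) k_omega w^2 + k_omega_G w dG
    (+ (1/2) k_G dG^2, which does not affect the minimizer) over the twist w at
    fixed groove change dG gives the closed form; a positive coupling with a
    widening groove therefore unwinds the helix.
    """
    if k_omega <= 0:
        raise ValueError(f"k_omega must be positive, got {k_omega}")
    return -(k_omega_g / k_omega) * d_g


def estimate_dG(
    f_t1: Quadratic, f_t2: Quadratic, t1: float, t2: float
) -> dict[str, float]:
    """Three estimators of the groove-minimum shift rate dG0/dT (nm per degree).

    (1) subtraction of the two fitted minima divided by the temperature
    difference; (2) and (3) the analytic rate evaluated at T1 and at T2 with
    the entropy deduced by subtraction.  Their average is returned under
    ``"average"``.  Celsius or Kelvin temperatures are accepted; only the
    difference enters.
    """
    s = entropy_between_temps(f_t1, f_t2, t1, t2)
    from_minima = (quadratic_minimum(f_t2) - quadratic_minimum(f_t1)) / (t2 - t1)
    rate_t1 = groove_shift_rate(f_t1, s, t1)
    rate_t2 = groove_shift_rate(f_t2, s, t2)
    values = [from_minima, rate_t1, rate_t2]
    return {
        "from_minima": float(from_minima),
        "rate_at_T1": float(rate_t1),
        "rate_at_T2": float(rate_t2),
        "average": float(np.mean(values)),
    }


@dataclass
class LinearEntropyFit:
    """Straight-line fit to S(G) samples, flagged when curvature is present."""

    slope: float            # k_SG = dS/dG of the linear fit
    intercept: float
    quad_coef: float        # quadratic coefficient of the full quadratic fit
    quad_tstat: float       # its t-statistic; large => the line is arbitrary
    quadratic_significant: bool


def fit_linear_entropy(
    g: np.ndarray, s_values: np.ndarray, t_threshold: float = 3.0
) -> LinearEntropyFit:
    """Fit S(G) by a line, reporting the significance of the quadratic term.

    When the underlying entropy is quadratic, the slope of a straight-line fit
    depends entirely on the sampled G window; the returned flag marks that
    situation (|t| of the quadratic coefficient above ``t_threshold``).
    """
    g = np.asarray(g, dtype=float)
    s = np.asarray(s_values, dtype=float)
    if np.unique(g).size < 3:
        raise ValueError("need >= 3 distinct G values")
    lin = np.polyfit(g, s, 1)
    if np.unique(g).size > 3:
        qcoef, qcov = np.polyfit(g, s, 2, cov=True)
        qsd = float(np.sqrt(qcov[0, 0]))
        tstat = qcoef[0] / qsd if qsd > 0 else np.inf
    else:  # exactly determined quadratic: no residual dof for a t-statistic
        qcoef = np.polyfit(g, s, 2)
        tstat = np.inf if abs(qcoef[0]) > 0 else 0.0
    # a numerically-zero curvature (exactly linear data) is never significant,
    # whatever the degenerate t-ratio says
    scale = max(1.0, float(np.abs(s).max()))
    significant = bool(abs(tstat) > t_threshold and abs(qcoef[0]) > 1e-9 * scale)
    if significant:
        warnings.warn(
            "entropy samples carry significant curvature: the slope of a "
            "linear fit is window-dependent and arbitrary",
            stacklevel=2,
        )
    return LinearEntropyFit(
        slope=float(lin[0]),
        intercept=float(lin[1]),
        quad_coef=float(qcoef[0]),
        quad_tstat=float(tstat),
        quadratic_significant=significant,
    )
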