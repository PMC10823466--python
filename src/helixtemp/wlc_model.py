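"""Inextensible wormlike-chain temperature model.

For a semiflexible polymer pulled by a force f satisfying f*P >> k_B*T, the
relative extension obeys

    z / L = 1 - sqrt(k_B * T / (4 f P)),        P = A_b / (k_B * T),

with P the bending persistence length (nm) and A_b the bending rigidity
(pN nm^2), a material property of the chain.  In terms of A_b the relation is
z/L = 1 - k_B*T / (2 sqrt(f * A_b)), which this module inverts in closed form
for two limiting mechanisms of an extension drop between two temperatures:

* :func:`solve_rigidity_change` -- contour length fixed, rigidity changes;
* :func:`solve_length_change` -- rigidity fixed, contour length changes.

Units: forces in pN, persistence length in nm, rigidity in pN nm^2,
extensions and contour lengths in um, temperature in K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "K_B",
    "WLCState",
    "WLCDomainError",
    "persistence_length",
    "bending_rigidity",
    "extension_ratio",
    "extension",
    "contour_length",
    "solve_rigidity_change",
    "solve_length_change",
]

#: Boltzmann constant, pN nm / K
K_B = 1.380649e-2

#: below f*P < soft_factor * k_B*T the high-force approximation is suspect
VALIDITY_FACTOR = 4.0


class WLCDomainError(ValueError):
    """Inputs leave the validity domain of the high-force WLC relation."""


@dataclass
class WLCState:
    """One wormlike-chain state (force pN, rigidity pN nm^2, temperature K,
    contour length um); extension is derived."""

    f: float
    A_b: float
    T: float
    L: float

    @property
    def P(self) -> float:
        return persistence_length(self.A_b, self.T)

    @property
    def z(self) -> float:
        return extension(self.f, self.A_b, self.T, self.L)


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name}: must be positive, got {value}")


def persistence_length(A_b: float, T: float) -> float:
    """P = A_b / (k_B T), nm."""
    _require_positive(A_b=A_b, T=T)
    return A_b / (K_B * T)


def bending_rigidity(P: float, T: float) -> float:
    """A_b = P k_B T, pN nm^2."""
    _require_positive(P=P, T=T)
    return P * K_B * T


def extension_ratio(f: float, A_b: float, T: float) -> float:
    """Relative extension z/L = 1 - k_B T / (2 sqrt(f A_b)).

    Warns when f*P < 4 k_B T (the high-force approximation degrades); raises
    :class:`WLCDomainError` when the ratio would leave (0, 1).
    """
    _require_positive(f=f, A_b=A_b, T=T)
    kbt = K_B * T
    p = persistence_length(A_b, T)
    if f * p < VALIDITY_FACTOR * kbt:
        warnings.warn(
            f"f*P = {f * p:.3g} pN nm is not >> k_B*T = {kbt:.3g} pN nm; "
            "the high-force WLC approximation may be inaccurate",
            stacklevel=2,
        )
    ratio = 1.0 - kbt / (2.0 * np.sqrt(f * A_b))
    if not 0.0 < ratio < 1.0:
        raise WLCDomainError(
            f"z/L = {ratio:.4g} outside (0, 1); inputs violate f*P >> k_B*T"
        )
    return float(ratio)


def extension(f: float, A_b: float, T: float, L: float) -> float:
    """Extension z (um) of a chain of contour length L (um)."""
    _require_positive(L=L)
    return L * extension_ratio(f, A_b, T)


def contour_length(z: float, f: float, A_b: float, T: float) -> float:
    """Contour length L (um) consistent with an observed extension z (um)."""
    _require_positive(z=z)
    return z / extension_ratio(f, A_b, T)


def solve_rigidity_change(
    z1: float, z2: float, T1: float, T2: float, f: float, A_b1: float
) -> float:
    """Bending rigidity A_b2 explaining an extension change at fixed contour.

    The contour length is fixed from state 1 (z1, T1, A_b1); A_b2 then solves
    the high-force WLC relation at (z2, T2, f, L) in closed form:
    A_b2 = (k_B T2 / (2 (1 - z2/L)))^2 / f.
    """
    _require_positive(z1=z1, z2=z2, T1=T1, T2=T2)
    L = contour_length(z1, f, A_b1, T1)
    r2 = z2 / L
    if not 0.0 < r2 < 1.0:
        raise WLCDomainError(
            f"required z2/L = {r2:.4g} outside (0, 1); no rigidity can explain it"
        )
    return float((K_B * T2 / (2.0 * (1.0 - r2))) ** 2 / f)


def solve_length_change(
    z1: float, z2: float, T1: float, T2: float, f: float, A_b: float
) -> float:
    """Fractional contour shortening 1 - L2/L1 at fixed bending rigidity.

    The contour lengths L1, L2 are inferred from the two observed extensions at
    their respective temperatures with the same A_b; the returned value is
    positive when the chain shortens.
    """
    _require_positive(z1=z1, z2=z2, T1=T1, T2=T2)
    L1 = contour_length(z1, f, A_b, T1)
    L2 = contour_length(z2, f, A_b, T2)
    return float(1.0 - L2 / L1)
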