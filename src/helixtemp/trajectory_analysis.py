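"""From per-snapshot geometry to twist-temperature slopes.

Pipeline: filter snapshots by Watson-Crick hydrogen-bond integrity (heavy-atom
distance < 4 A, every pair in the analyzed range intact), average the global
twist series with the half-trajectory error rule, regress mean twist on
temperature, and normalize the slope to degrees per Celsius per kilobase pair.
The slope-vs-rise relation across duplex variants is fitted by ordinary least
squares as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic_data import DuplexAtoms
from .templates import RES_NAME_TO_BASE, WC_BONDS

__all__ = [
    "HBOND_CUTOFF",
    "END_EXCLUSION",
    "TwistSeries",
    "SlopeFit",
    "analysis_range",
    "wc_hbond_mask",
    "series_mean_with_half_error",
    "fit_twist_vs_temperature",
    "slope_vs_rise_fit",
]

#: heavy-atom donor-acceptor distance below which a hydrogen bond is present (A)
HBOND_CUTOFF = 4.0

#: pairs excluded at each duplex end when deriving the analyzed range
END_EXCLUSION = 3


def analysis_range(n_bp: int, exclude_ends: int = END_EXCLUSION) -> tuple[int, int]:
    """Closed 1-based pair range after excluding ``exclude_ends`` pairs per end."""
    first, last = 1 + exclude_ends, n_bp - exclude_ends
    if last - first < 1:
        raise ValueError(f"duplex of {n_bp} bp too short for the exclusion rule")
    return first, last


@dataclass
class TwistSeries:
    """Per-snapshot global twist of one trajectory at one temperature."""

    twist: np.ndarray           # degrees
    hbond_mask: np.ndarray      # True = snapshot kept
    temperature: float          # Celsius
    n_steps: int                # steps spanned by the analyzed range

    def __post_init__(self) -> None:
        self.twist = np.asarray(self.twist, dtype=float)
        self.hbond_mask = np.asarray(self.hbond_mask, dtype=bool)
        if self.twist.shape != self.hbond_mask.shape:
            raise ValueError("mask length must equal series length")

    @property
    def filtered(self) -> np.ndarray:
        out = self.twist[self.hbond_mask]
        if out.size == 0:
            raise ValueError("hydrogen-bond filter removed every snapshot")
        return out

    @property
    def kept_fraction(self) -> float:
        return float(self.hbond_mask.mean())


@dataclass
class SlopeFit:
    """Ordinary least-squares slope with the 2 x SD error convention."""

    slope: float            # raw units (deg/C, or turns/C for tweezer data)
    intercept: float
    slope_sd: float
    r_squared: float
    slope_per_kbp: float | None = None      # deg/(C*kbp)
    slope_per_kbp_sd: float | None = None
    n_points: int = 0

    @property
    def reported_error(self) -> float:
        """Twice the slope standard deviation (~95% confidence interval)."""
        return 2.0 * self.slope_sd

    @property
    def reported_error_per_kbp(self) -> float | None:
        if self.slope_per_kbp_sd is None:
            return None
        return 2.0 * self.slope_per_kbp_sd


def wc_hbond_mask(
    atoms: DuplexAtoms,
    first: int | None = None,
    last: int | None = None,
    cutoff: float = HBOND_CUTOFF,
) -> tuple[np.ndarray, np.ndarray]:
    """Watson-Crick integrity masks from heavy-atom donor-acceptor distances.

    A pair is intact iff every one of its WC hydrogen-bond heavy-atom distances
    is strictly below ``cutoff`` (A.T/A.U: 2 bonds, G.C: 3).  A snapshot passes
    iff all pairs in the closed range [first, last] are intact (defaults to the
    standard end-exclusion range).

    Returns ``(pair_intact, snapshot_ok)`` with shapes (n_snapshots, n_pairs)
    and (n_snapshots,).
    """
    n_bp = atoms.n_bp
    if first is None or last is None:
        first, last = analysis_range(n_bp)
    pairs = range(first, last + 1)
    idx_a: list[int] = []
    idx_b: list[int] = []
    bond_pair: list[int] = []
    for p in pairs:
        try:
            i_w = np.flatnonzero((atoms.chain_ids == "A") & (atoms.res_ids == p))
            i_c = np.flatnonzero(
                (atoms.chain_ids == "B") & (atoms.res_ids == n_bp + 1 - p)
            )
            base_w = RES_NAME_TO_BASE[str(atoms.res_names[i_w[0]])]
            base_c = RES_NAME_TO_BASE[str(atoms.res_names[i_c[0]])]
        except (IndexError, KeyError) as exc:
            raise ValueError(f"pair {p}: residues not found ({exc})") from None
        try:
            bonds = WC_BONDS[(base_w, base_c)]
        except KeyError:
            raise ValueError(
                f"pair {p}: no Watson-Crick bond table for {base_w}-{base_c}"
            ) from None
        for a_w, a_c in bonds:
            try:
                idx_a.append(atoms.atom_index("A", p, a_w))
                idx_b.append(atoms.atom_index("B", n_bp + 1 - p, a_c))
            except KeyError:
                raise ValueError(
                    f"pair {p} ({base_w}-{base_c}): missing atom {a_w}/{a_c}"
                ) from None
            bond_pair.append(p - first)

    d = np.linalg.norm(
        atoms.coords[:, idx_a] - atoms.coords[:, idx_b], axis=-1
    )  # (S, n_bonds)
    bond_ok = d < cutoff
    n_pairs = last - first + 1
    pair_intact = np.ones((atoms.n_snapshots, n_pairs), dtype=bool)
    bp = np.asarray(bond_pair)
    for j in range(n_pairs):
        sel = bp == j
        pair_intact[:, j] = bond_ok[:, sel].all(axis=1)
    snapshot_ok = pair_intact.all(axis=1)
    return pair_intact, snapshot_ok


def series_mean_with_half_error(values: np.ndarray) -> tuple[float, float]:
    """Mean of a series with the half-trajectory error estimate.

    The error is the mean absolute difference between the whole-series mean and
    the means of its two halves, split at the midpoint (odd lengths give the
    extra element to the first half).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("series must have >= 2 elements")
    m = float(v.mean())
    cut = v.size - v.size // 2  # first half gets the extra element
    m1 = float(v[:cut].mean())
    m2 = float(v[cut:].mean())
    err = 0.5 * (abs(m - m1) + abs(m - m2))
    return m, err


def fit_twist_vs_temperature(
    temperatures: np.ndarray,
    mean_twists: np.ndarray,
    n_steps: int,
) -> SlopeFit:
    """Unweighted OLS of mean global twist (degrees) on temperature (Celsius).

    The normalized slope divides by the number of steps spanned and scales to
    1000 steps, giving degrees/(C*kbp).
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(mean_twists, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 temperatures")
    if np.unique(t).size < 3:
        raise ValueError("temperatures must be distinct")
    res = stats.linregress(t, y)
    scale = 1000.0 / n_steps
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_sd=float(res.stderr),
        r_squared=float(res.rvalue**2),
        slope_per_kbp=float(res.slope * scale),
        slope_per_kbp_sd=float(res.stderr * scale),
        n_points=t.size,
    )


def slope_vs_rise_fit(
    rises: np.ndarray,
    slopes: np.ndarray,
    predict_at: float | None = None,
) -> tuple[SlopeFit, float | None]:
    """OLS of normalized twist-temperature slope on mean helical rise.

    Returns the fit (with R^2) and, optionally, the predicted slope at a
    queried rise such as the consensus 2.8 A.
    """
    x = np.asarray(rises, dtype=float)
    y = np.asarray(slopes, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: no variance in rise")
    res = stats.linregress(x, y)
    r2 = 1.0 if x.size == 2 else float(res.rvalue**2)
    fit = SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_sd=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        r_squared=r2,
        n_points=x.size,
    )
    pred = None
    if predict_at is not None:
        pred = float(res.slope * predict_at + res.intercept)
    return fit, pred
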