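"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators stand in for the study's raw data:

* :func:`make_helix_trajectory` -- snapshot ensembles of a ~30 bp duplex built
  by composing per-step rigid transforms (mean twist with a linear temperature
  trend, mean rise, independent Gaussian fluctuations on twist, rise and axis
  tilt) with a minimal rigid atom model per base and a plantable fraction of
  broken Watson-Crick pairs;
* :func:`make_rotation_extension_trace` -- Gaussian-shaped magnetic-tweezer
  extension-vs-turns curves with additive noise;
* :func:`make_groove_surface` -- quadratic free-energy surfaces
  F(G, T) = U(G) - T*S(G) sampled on a groove-width grid.

All generators are driven by ``numpy.random.default_rng`` seeded from the spec,
so identical inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .frame_geometry import FrameTrajectory
from .templates import (
    FLIP,
    RES_NAME_DNA,
    RES_NAME_RNA,
    complement,
    template_coords,
)

__all__ = [
    "DEFAULT_SEQUENCE_33",
    "BROKEN_PAIR_OFFSET",
    "HelixSpec",
    "SyntheticTruth",
    "DuplexAtoms",
    "make_helix_trajectory",
    "make_temperature_ensemble",
    "make_rotation_extension_trace",
    "make_groove_surface",
]

#: reference-strand sequence of the 33-mer duplex used throughout (RNA form)
DEFAULT_SEQUENCE_33 = "GAGAUGCUAACCCUGAUCGCUGAUUCCUUGGAC"

#: extra displacement (Angstrom) applied along the hydrogen-bond direction to a
#: planted broken pair; chosen to push every WC heavy-atom distance at least
#: 1 A beyond the 4 A detection cutoff
BROKEN_PAIR_OFFSET = 2.5


@dataclass(frozen=True)
class HelixSpec:
    """Ground-truth parameters of a synthetic duplex ensemble.

    ``twist_per_step`` and ``rise_per_step`` are the mean step parameters at the
    reference temperature ``t_ref``; ``twist_temp_slope`` shifts the mean twist
    linearly with temperature (degrees per Celsius per step).  ``twist_sd``,
    ``rise_sd`` and ``tilt_sd`` are per-step Gaussian fluctuation scales
    (degrees, Angstrom, degrees).  ``broken_pair_rate`` is the independent
    per-(snapshot, pair) probability of planting a broken Watson-Crick pair.
    """

    n_bp: int = 33
    sequence: str | None = None
    twist_per_step: float = 32.7
    rise_per_step: float = 2.8
    twist_sd: float = 4.0
    rise_sd: float = 0.2
    tilt_sd: float = 2.0
    twist_temp_slope: float = -0.0143
    broken_pair_rate: float = 0.0
    n_snapshots: int = 200
    seed: int = 0
    t_ref: float = 27.0

    def __post_init__(self) -> None:
        if self.sequence is not None:
            seq = self.sequence.upper()
            if not set(seq) <= set("ACGUT"):
                raise ValueError(f"sequence: letters must be in ACGUT, got {seq!r}")
            if len(seq) != self.n_bp:
                object.__setattr__(self, "n_bp", len(seq))
            object.__setattr__(self, "sequence", seq)
        if self.n_bp < 4:
            raise ValueError(f"n_bp: must be >= 4, got {self.n_bp}")
        if not 0.0 <= self.broken_pair_rate < 1.0:
            raise ValueError(
                f"broken_pair_rate: must be in [0, 1), got {self.broken_pair_rate}"
            )
        if self.rise_per_step <= 0:
            raise ValueError(f"rise_per_step: must be > 0, got {self.rise_per_step}")
        for name in ("twist_sd", "rise_sd", "tilt_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0, got {getattr(self, name)}")
        if self.n_snapshots < 1:
            raise ValueError(f"n_snapshots: must be >= 1, got {self.n_snapshots}")

    @property
    def resolved_sequence(self) -> str:
        """The reference-strand sequence, tiling the default 33-mer if unset."""
        if self.sequence is not None:
            return self.sequence
        reps = -(-self.n_bp // len(DEFAULT_SEQUENCE_33))
        return (DEFAULT_SEQUENCE_33 * reps)[: self.n_bp]

    @property
    def is_rna(self) -> bool:
        return "T" not in self.resolved_sequence

    def mean_twist_at(self, temperature: float) -> float:
        """Planted mean step twist (degrees) at a temperature in Celsius."""
        return self.twist_per_step + self.twist_temp_slope * (temperature - self.t_ref)


@dataclass
class SyntheticTruth:
    """Ground truth returned alongside a generated trajectory."""

    step_twists: np.ndarray   # (n_snapshots, n_bp - 1), degrees
    step_rises: np.ndarray    # (n_snapshots, n_bp - 1), Angstrom
    broken: np.ndarray        # (n_snapshots, n_bp), bool
    temperature: float        # Celsius
    mean_step_twist: float    # planted mean at this temperature, degrees
    rise_per_step: float
    twist_temp_slope: float
    t_ref: float

    def global_twist(self, first: int, last: int) -> np.ndarray:
        """True per-snapshot global twist (sum of planted step twists) over
        the closed pair range [first, last]."""
        return self.step_twists[:, first - 1 : last - 1].sum(axis=1)

    def mean_hrise(self, first: int, last: int) -> np.ndarray:
        return self.step_rises[:, first - 1 : last - 1].mean(axis=1)

    def snapshot_intact(self, first: int, last: int) -> np.ndarray:
        """True per-snapshot mask: no broken pair within [first, last]."""
        return ~self.broken[:, first - 1 : last].any(axis=1)

    def to_dict(self) -> dict:
        return {
            "temperature_C": self.temperature,
            "mean_step_twist_deg": self.mean_step_twist,
            "rise_per_step_A": self.rise_per_step,
            "twist_temp_slope_deg_per_C_per_step": self.twist_temp_slope,
            "t_ref_C": self.t_ref,
            "step_twists_deg": self.step_twists.tolist(),
            "step_rises_A": self.step_rises.tolist(),
            "broken": self.broken.tolist(),
        }


@dataclass
class DuplexAtoms:
    """Minimal rigid atom trajectory for one duplex (both strands).

    ``coords`` has shape (n_snapshots, n_atoms, 3), Angstrom.  Chain A is the
    reference strand 5'->3' (residues 1..n); chain B is the complementary
    strand in its own 5'->3' order, so chain B residue j pairs with chain A
    residue n + 1 - j.
    """

    coords: np.ndarray
    atom_names: np.ndarray
    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_names = np.asarray(self.atom_names)
        self.chain_ids = np.asarray(self.chain_ids)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names)

    @property
    def n_snapshots(self) -> int:
        return self.coords.shape[0]

    @property
    def n_bp(self) -> int:
        return int(self.res_ids[self.chain_ids == "A"].max())

    def atom_index(self, chain: str, res_id: int, atom_name: str) -> int:
        hits = np.flatnonzero(
            (self.chain_ids == chain)
            & (self.res_ids == res_id)
            & (self.atom_names == atom_name)
        )
        if hits.size == 0:
            raise KeyError(f"atom {atom_name} of {chain}/{res_id} not found")
        return int(hits[0])


def _rng_for(seed: int, temperature: float) -> np.random.Generator:
    t_key = int(round(temperature * 1000))
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), abs(t_key), 1 if t_key < 0 else 0])
    )


def _rot_z(angles_rad: np.ndarray) -> np.ndarray:
    c, s = np.cos(angles_rad), np.sin(angles_rad)
    out = np.zeros(angles_rad.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    out[..., 2, 2] = 1.0
    return out


def _rot_x(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = 1.0
    out[..., 1, 1] = c
    out[..., 1, 2] = -s
    out[..., 2, 1] = s
    out[..., 2, 2] = c
    return out


def _rot_y(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 1, 1] = 1.0
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def make_helix_trajectory(
    spec: HelixSpec,
    temperature: float,
    with_atoms: bool = True,
) -> tuple[FrameTrajectory, DuplexAtoms | None, SyntheticTruth]:
    """Generate one duplex snapshot ensemble at one temperature (Celsius).

    Per snapshot, pair frames are built by composing per-step rigid transforms:
    a rotation ``Rz(twist) @ Rx(tilt_x) @ Ry(tilt_y)`` followed by a rise
    translation along the local z-axis.  Twist is drawn from
    ``N(mean_twist_at(T), twist_sd)``, rise from ``N(rise_per_step, rise_sd)``
    and each tilt component from ``N(0, tilt_sd)``.  A minimal heavy-atom base
    model is placed rigidly in each pair frame (the complementary base via the
    y,z-flip); pairs flagged broken have their complementary base displaced by
    ``BROKEN_PAIR_OFFSET`` along the hydrogen-bond direction.
    """
    if not np.isfinite(temperature):
        raise ValueError(f"temperature: must be finite, got {temperature}")
    rng = _rng_for(spec.seed, temperature)
    n_steps = spec.n_bp - 1
    S = spec.n_snapshots
    mean_twist = spec.mean_twist_at(temperature)

    step_twists = rng.normal(mean_twist, spec.twist_sd, size=(S, n_steps))
    step_rises = rng.normal(spec.rise_per_step, spec.rise_sd, size=(S, n_steps))
    tilt_x = np.radians(rng.normal(0.0, spec.tilt_sd, size=(S, n_steps)))
    tilt_y = np.radians(rng.normal(0.0, spec.tilt_sd, size=(S, n_steps)))
    broken = rng.random(size=(S, spec.n_bp)) < spec.broken_pair_rate

    r_steps = (
        _rot_z(np.radians(step_twists)) @ _rot_x(tilt_x) @ _rot_y(tilt_y)
    )

    triads = np.empty((S, spec.n_bp, 3, 3))
    origins = np.empty((S, spec.n_bp, 3))
    triads[:, 0] = np.eye(3)
    origins[:, 0] = 0.0
    for i in range(n_steps):
        origins[:, i + 1] = (
            origins[:, i] + step_rises[:, i, None] * triads[:, i, :, 2]
        )
        triads[:, i + 1] = triads[:, i] @ r_steps[:, i]

    traj = FrameTrajectory(origins, triads, sequence=spec.resolved_sequence,
                           temperature=float(temperature))
    truth = SyntheticTruth(
        step_twists=step_twists,
        step_rises=step_rises,
        broken=broken,
        temperature=float(temperature),
        mean_step_twist=mean_twist,
        rise_per_step=spec.rise_per_step,
        twist_temp_slope=spec.twist_temp_slope,
        t_ref=spec.t_ref,
    )
    atoms = _place_atoms(spec, traj, broken) if with_atoms else None
    return traj, atoms, truth


def _place_atoms(
    spec: HelixSpec, traj: FrameTrajectory, broken: np.ndarray
) -> DuplexAtoms:
    seq = spec.resolved_sequence
    rna = spec.is_rna
    res_table = RES_NAME_RNA if rna else RES_NAME_DNA
    n = spec.n_bp

    # local coordinates of every atom, grouped per pair (W then C bases)
    names: list[str] = []
    chains: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    pair_of_atom: list[int] = []
    local: list[np.ndarray] = []
    comp_mask: list[bool] = []

    # chain A, 5'->3'
    for i, b in enumerate(seq, start=1):
        a_names, a_xyz = template_coords(b)
        names += a_names
        chains += ["A"] * len(a_names)
        resids += [i] * len(a_names)
        resnames += [res_table[b]] * len(a_names)
        pair_of_atom += [i] * len(a_names)
        local.append(a_xyz)
        comp_mask += [False] * len(a_names)
    # chain B in its own 5'->3' order: residue j pairs with A residue n+1-j
    for j in range(1, n + 1):
        i = n + 1 - j
        b = complement(seq[i - 1], rna=rna)
        a_names, a_xyz = template_coords(b)
        names += a_names
        chains += ["B"] * len(a_names)
        resids += [j] * len(a_names)
        resnames += [res_table[b]] * len(a_names)
        pair_of_atom += [i] * len(a_names)
        local.append(a_xyz @ FLIP.T)  # complementary base: flip into pair frame
        comp_mask += [True] * len(a_names)

    local_xyz = np.concatenate(local, axis=0)  # (n_atoms, 3) in pair frames
    pair_idx = np.asarray(pair_of_atom) - 1    # (n_atoms,)
    comp_mask = np.asarray(comp_mask)

    # lab coords: R_pair @ local + origin, per snapshot
    R = traj.triads[:, pair_idx]               # (S, n_atoms, 3, 3)
    o = traj.origins[:, pair_idx]              # (S, n_atoms, 3)
    coords = np.einsum("saij,aj->sai", R, local_xyz) + o

    if broken.any():
        # displace the complementary base along -y of the pair frame, which is
        # the hydrogen-bond direction pointing away from the reference base
        y_axes = traj.triads[:, :, :, 1]       # (S, n_bp, 3)
        disp = -BROKEN_PAIR_OFFSET * y_axes * broken[:, :, None]
        coords += disp[:, pair_idx] * comp_mask[None, :, None]

    return DuplexAtoms(
        coords=coords,
        atom_names=np.asarray(names),
        chain_ids=np.asarray(chains),
        res_ids=np.asarray(resids),
        res_names=np.asarray(resnames),
    )


def make_temperature_ensemble(
    spec: HelixSpec,
    temperatures: list[float],
    with_atoms: bool = True,
) -> list[tuple[FrameTrajectory, DuplexAtoms | None, SyntheticTruth]]:
    """One trajectory per temperature (Celsius), sharing the spec.

    The planted mean twists fall exactly on the line
    ``twist_per_step + twist_temp_slope * (T - t_ref)``.
    """
    temps = list(temperatures)
    if len(set(temps)) < 2:
        raise ValueError("need >= 2 distinct temperatures")
    return [make_helix_trajectory(spec, t, with_atoms=with_atoms) for t in temps]


def make_rotation_extension_trace(
    center: float,
    width: float,
    max_ext: float,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    turns_range: tuple[float, float] = (-20.0, 20.0),
    n_points: int = 81,
    temperature: float | None = None,
    tether_id: str = "t0",
    tether_length_kbp: float = 3.3,
    seed: int = 0,
):
    """Gaussian-shaped magnetic-tweezer rotation-extension trace.

    Extension (um) is sampled as
    ``baseline + max_ext * exp(-(n - center)^2 / (2 width^2))`` on a uniform
    turns grid, plus i.i.d. Gaussian noise of scale ``noise_sd``.
    """
    from .mt_analysis import RotExtCurve

    if width <= 0:
        raise ValueError(f"width: must be > 0, got {width}")
    if n_points < 7:
        raise ValueError(f"n_points: must be >= 7, got {n_points}")
    turns = np.linspace(turns_range[0], turns_range[1], n_points)
    ext = baseline + max_ext * np.exp(-((turns - center) ** 2) / (2.0 * width**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ext = ext + rng.normal(0.0, noise_sd, size=n_points)
    return RotExtCurve(
        turns=turns,
        extension=ext,
        temperature=temperature,
        tether_id=tether_id,
        tether_length_kbp=tether_length_kbp,
    )


def make_groove_surface(
    u_coeffs: tuple[float, float, float],
    s_coeffs: tuple[float, float, float],
    temperatures: list[float],
    g_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tabulate F(G, T) = U(G) - T*S(G) (+ noise) on a groove-width grid.

    ``temperatures`` are absolute (K); ``g_grid`` is in nm.  The leading
    coefficient of U - T*S must stay positive (convex surface) at every
    requested temperature.  Returns a tidy DataFrame with columns ``G_nm``,
    ``F_pNnm``, ``T_K``.
    """
    ua, ub, uc = (float(v) for v in u_coeffs)
    sa, sb, sc = (float(v) for v in s_coeffs)
    g = np.asarray(g_grid, dtype=float)
    rng = np.random.default_rng(seed)
    frames = []
    for T in temperatures:
        lead = ua - T * sa
        if lead <= 0:
            raise ValueError(
                f"surface is not convex at T = {T} K (leading coefficient {lead})"
            )
        f = (ua - T * sa) * g**2 + (ub - T * sb) * g + (uc - T * sc)
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, size=g.shape)
        frames.append(pd.DataFrame({"G_nm": g, "F_pNnm": f, "T_K": float(T)}))
    return pd.concat(frames, ignore_index=True)
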