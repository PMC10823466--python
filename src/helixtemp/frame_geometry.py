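"""Base-pair reference frames and global twist definitions.

A base-pair frame is an orthonormal right-handed triad (columns x, y, z) plus an
origin, attached to a base pair by least-squares superposition of the embedded
standard-base templates.  From per-pair frames this module derives

* the local (mean-plane) twist between consecutive pairs: the signed angle
  between the x-axes measured in the plane whose normal is the mean of the two
  z-axes;
* the screw decomposition of each base-pair step: rotation angle about the screw
  axis (helical twist, h-twist) and translation along it (helical rise, h-rise);
* local helical axes (average of the two step screw axes flanking a pair);
* projected end frames and the global end-to-end twist of a duplex fragment,
  unwrapped to the multiple of 360 degrees nearest the accumulated local twist.

Angles are in degrees, right-handed twist positive; distances in Angstrom.
Pair indices are 1-based along the reference strand; analyzed ranges are closed
intervals that must exclude at least enough terminal pairs for each end pair to
have two flanking steps (three excluded pairs per end in the standard protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .templates import FLIP, template_coords

__all__ = [
    "GeometryError",
    "BasePairFrame",
    "StepParams",
    "GlobalTwist",
    "FrameTrajectory",
    "fit_base_frame",
    "pair_midframe",
    "mean_plane_twist",
    "step_screw_axis",
    "local_helical_axis",
    "project_frame_to_axis",
    "end_to_end_twist",
    "global_twist_series",
]

#: screw decompositions with |rotation| below this (degrees) use the
#: pure-translation branch (the axis direction is numerically unstable there)
DEGENERATE_TWIST_DEG = 0.01

_ORTHO_TOL = 1e-6


class GeometryError(ValueError):
    """Degenerate or invalid geometry (collinear atoms, antiparallel axes...)."""


def _check_triad(triad: np.ndarray) -> np.ndarray:
    triad = np.asarray(triad, dtype=float)
    if triad.shape != (3, 3):
        raise GeometryError(f"triad must be 3x3, got shape {triad.shape}")
    if not np.allclose(triad.T @ triad, np.eye(3), atol=_ORTHO_TOL):
        raise GeometryError("triad is not orthonormal")
    if not np.isclose(np.linalg.det(triad), 1.0, atol=1e-6):
        raise GeometryError("triad is not right-handed (det != +1)")
    return triad


@dataclass
class BasePairFrame:
    """Orthonormal triad + origin for one base pair in one snapshot.

    ``triad`` columns are the x, y, z axes expressed in lab coordinates; ``z``
    points 5'->3' along the reference strand.
    """

    origin: np.ndarray
    triad: np.ndarray
    pair_index: int = 0
    snapshot_index: int = 0
    rmsd: float | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.triad = _check_triad(self.triad)

    @property
    def x(self) -> np.ndarray:
        return self.triad[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.triad[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.triad[:, 2]


@dataclass
class StepParams:
    """Local and helical parameters of one base-pair step."""

    local_twist: float  # degrees, mean-plane angle between the pair frames
    h_twist: float      # degrees, rotation about the screw axis
    h_rise: float       # Angstrom, translation along the screw axis
    axis: np.ndarray    # unit vector, lab coordinates

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)


@dataclass
class GlobalTwist:
    """Global twist of one duplex snapshot over a closed pair range."""

    end_to_end_twist: float  # degrees, unwrapped
    htwist_sum: float        # degrees
    mean_hrise: float        # Angstrom
    first: int               # analyzed range, 1-based inclusive
    last: int


@dataclass
class FrameTrajectory:
    """Per-snapshot base-pair frames for one duplex at one temperature.

    ``triads`` has shape (n_snapshots, n_bp, 3, 3) with axis columns x, y, z;
    ``origins`` has shape (n_snapshots, n_bp, 3), Angstrom.
    """

    origins: np.ndarray
    triads: np.ndarray
    sequence: str = ""
    temperature: float | None = None  # Celsius

    def __post_init__(self) -> None:
        self.origins = np.asarray(self.origins, dtype=float)
        self.triads = np.asarray(self.triads, dtype=float)
        if self.origins.ndim != 3 or self.origins.shape[-1] != 3:
            raise ValueError("origins must have shape (n_snapshots, n_bp, 3)")
        if self.triads.shape != self.origins.shape + (3,):
            raise ValueError("triads must have shape (n_snapshots, n_bp, 3, 3)")

    @property
    def n_snapshots(self) -> int:
        return self.origins.shape[0]

    @property
    def n_bp(self) -> int:
        return self.origins.shape[1]

    def frame(self, snapshot: int, pair_index: int) -> BasePairFrame:
        """Single frame; ``pair_index`` is 1-based along the reference strand."""
        i = pair_index - 1
        return BasePairFrame(
            self.origins[snapshot, i],
            self.triads[snapshot, i],
            pair_index=pair_index,
            snapshot_index=snapshot,
        )

    def snapshot_frames(self, snapshot: int) -> list[BasePairFrame]:
        return [self.frame(snapshot, i + 1) for i in range(self.n_bp)]


# ---------------------------------------------------------------------------
# frame fitting


def fit_base_frame(
    coords: np.ndarray, atom_names: list[str], base: str
) -> BasePairFrame:
    """Fit the standard-base reference frame to observed base atoms.

    Finds the rigid transform (rotation R, origin t) minimizing the RMSD between
    the embedded template for ``base`` and the observed ``coords`` (Kabsch
    least-squares superposition); the frame triad is R and the origin is the
    image of the template origin.

    Parameters
    ----------
    coords : (n, 3) array, Angstrom, lab coordinates.
    atom_names : names matching the template atom names; at least three matched,
        non-collinear atoms are required.
    base : base identity, one of A, C, G, T, U.
    """
    tmpl_names, tmpl = template_coords(base)
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(atom_names) != len(coords):
        raise ValueError("atom_names and coords length mismatch")
    idx_pairs = [
        (i, tmpl_names.index(n)) for i, n in enumerate(atom_names) if n in tmpl_names
    ]
    if len(idx_pairs) < 3:
        raise GeometryError(
            f"need >=3 atoms matching the {base} template, got {len(idx_pairs)}"
        )
    obs = coords[[i for i, _ in idx_pairs]]
    ref = tmpl[[j for _, j in idx_pairs]]
    obs_c = obs - obs.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # collinear observed atoms leave the rotation about the line undetermined
    sv = np.linalg.svd(obs_c, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise GeometryError(f"observed atoms for base {base} are collinear")
    rot, rssd = Rotation.align_vectors(obs_c, ref_c)
    R = rot.as_matrix()
    origin = obs.mean(axis=0) - R @ ref.mean(axis=0)
    rmsd = float(rssd / np.sqrt(len(obs)))
    return BasePairFrame(origin, R, rmsd=rmsd)


def pair_midframe(frame_w: BasePairFrame, frame_c: BasePairFrame) -> BasePairFrame:
    """Average a reference-strand base frame with its complementary partner.

    The complementary frame (given in its own strand convention, z along its own
    5'->3' direction) is first flipped by 180 degrees about its x-axis (y and z
    columns negated), then combined with the reference frame through the
    half-rotation between the two triads.  The origin is the midpoint.
    """
    r_w = frame_w.triad
    r_cf = frame_c.triad @ FLIP
    r_rel = r_w.T @ r_cf
    half = Rotation.from_rotvec(Rotation.from_matrix(r_rel).as_rotvec() / 2.0)
    triad = r_w @ half.as_matrix()
    origin = 0.5 * (frame_w.origin + frame_c.origin)
    idx = frame_w.pair_index
    return BasePairFrame(origin, triad, pair_index=idx,
                         snapshot_index=frame_w.snapshot_index)


# ---------------------------------------------------------------------------
# batch kernels (scalar operations are thin wrappers over these)


def _hinge_into_plane(x, z, n):
    """Carry x into the plane normal to n by the minimal rotation taking z to n.

    The hinge axis is z x n; because x is perpendicular to z, the rotated
    vector lies exactly in the plane.  Rodrigues' formula, broadcast over
    leading dimensions.
    """
    k = np.cross(z, n)
    s = np.linalg.norm(k, axis=-1, keepdims=True)  # sin(hinge angle)
    c = np.sum(z * n, axis=-1, keepdims=True)      # cos(hinge angle)
    ku = np.where(s > 1e-12, k / np.maximum(s, 1e-300), 0.0)
    return x * c + np.cross(ku, x) * s + ku * np.sum(ku * x, axis=-1, keepdims=True) * (1.0 - c)


def _mean_plane_angle(x1, z1, x2, z2):
    """Signed angle (degrees) from x1 to x2 in the plane normal to mean(z1, z2).

    Each x-axis is carried into the mean plane by the minimal (hinge) rotation
    taking its own z onto the plane normal, as in the 3DNA local-twist
    algorithm; the signed angle between the carried x-axes is then measured
    about the normal.  This construction makes the angle change by exactly the
    offset when either frame is rotated about its own z-axis — the property
    behind the offset-rotation invariance of end-to-end twist changes.
    Broadcasts over leading dimensions; raises for antiparallel z-axes.
    """
    mz = z1 + z2
    nrm = np.linalg.norm(mz, axis=-1, keepdims=True)
    if np.any(nrm < 1e-8):
        raise GeometryError("z-axes are antiparallel: mean plane undefined")
    mz = mz / nrm
    p1 = _hinge_into_plane(x1, z1, mz)
    p2 = _hinge_into_plane(x2, z2, mz)
    cosv = np.sum(p1 * p2, axis=-1)
    sinv = np.sum(np.cross(p1, p2) * mz, axis=-1)
    return np.degrees(np.arctan2(sinv, cosv))


def _batch_screw(r_a, r_b, o_a, o_b):
    """Screw decomposition of the transforms taking frames a to frames b.

    Inputs broadcast as (..., 3, 3) triads and (..., 3) origins.  Returns
    (h_twist degrees, h_rise Angstrom, axis in lab coordinates).
    """
    r_rel = np.einsum("...ji,...jk->...ik", r_a, r_b)
    d_lab = o_b - o_a
    t_rel = np.einsum("...ji,...j->...i", r_a, d_lab)
    shape = r_rel.shape[:-2]
    rv = Rotation.from_matrix(r_rel.reshape(-1, 3, 3)).as_rotvec().reshape(shape + (3,))
    angle = np.linalg.norm(rv, axis=-1)
    h_twist = np.degrees(angle)
    small = h_twist < DEGENERATE_TWIST_DEG
    with np.errstate(invalid="ignore", divide="ignore"):
        axis_local = rv / angle[..., None]
    if np.any(small):
        # pure-translation branch: axis along the step translation
        t_nrm = np.linalg.norm(t_rel, axis=-1)
        fallback = np.where(
            t_nrm[..., None] > 1e-12,
            t_rel / np.maximum(t_nrm, 1e-300)[..., None],
            np.broadcast_to([0.0, 0.0, 1.0], t_rel.shape),
        )
        axis_local = np.where(small[..., None], fallback, axis_local)
        h_twist = np.where(small, 0.0, h_twist)
    h_rise = np.sum(t_rel * axis_local, axis=-1)
    axis_lab = np.einsum("...ij,...j->...i", r_a, axis_local)
    return h_twist, h_rise, axis_lab


def _project_triads(triads, axes):
    """Project triads so z == axis, keeping the in-plane part of x (batched)."""
    x = triads[..., :, 0]
    z = triads[..., :, 2]
    if np.any(np.sum(z * axes, axis=-1) < -1.0 + 1e-8):
        raise GeometryError("frame z antiparallel to the projection axis")
    xp = x - np.sum(x * axes, axis=-1, keepdims=True) * axes
    nrm = np.linalg.norm(xp, axis=-1, keepdims=True)
    if np.any(nrm < 1e-8):
        raise GeometryError("frame x parallel to the projection axis")
    xp = xp / nrm
    yp = np.cross(axes, xp)
    return np.stack([xp, yp, axes], axis=-1)


# ---------------------------------------------------------------------------
# scalar operations


def mean_plane_twist(frame_a: BasePairFrame, frame_b: BasePairFrame) -> float:
    """Local twist (degrees, in (-180, 180]) between two base-pair frames.

    Both x-axes are carried into the plane normal to the normalized mean of
    the two z-axes (minimal hinge rotations, as in the 3DNA local twist); the
    result is the signed angle from the carried ``frame_a.x`` to the carried
    ``frame_b.x`` about that normal.
    """
    return float(_mean_plane_angle(frame_a.x, frame_a.z, frame_b.x, frame_b.z))


def step_screw_axis(frame_i: BasePairFrame, frame_j: BasePairFrame) -> StepParams:
    """Screw decomposition of the base-pair step from ``frame_i`` to ``frame_j``.

    The relative rigid transform is decomposed into a rotation ``h_twist`` about
    the screw axis and a translation ``h_rise`` along it; the axis is oriented
    so that ``h_twist >= 0`` for right-handed steps.  Below
    ``DEGENERATE_TWIST_DEG`` the pure-translation branch is used.
    """
    h_twist, h_rise, axis = _batch_screw(
        frame_i.triad, frame_j.triad, frame_i.origin, frame_j.origin
    )
    local = mean_plane_twist(frame_i, frame_j)
    return StepParams(local, float(h_twist), float(h_rise), axis)


def local_helical_axis(frames: list[BasePairFrame], pair_index: int) -> np.ndarray:
    """Local helical axis at a pair: normalized mean of its two step screw axes.

    ``frames`` is the full snapshot frame list; ``pair_index`` is 1-based and
    must have a neighbour on each side.
    """
    i = pair_index - 1
    if i < 1 or i > len(frames) - 2:
        raise GeometryError(
            f"pair {pair_index} lacks two flanking steps (1 < index < {len(frames)})"
        )
    a1 = step_screw_axis(frames[i - 1], frames[i]).axis
    a2 = step_screw_axis(frames[i], frames[i + 1]).axis
    mean = a1 + a2
    nrm = np.linalg.norm(mean)
    if nrm < 1e-8:
        raise GeometryError("step axes are antiparallel: local axis undefined")
    return mean / nrm


def project_frame_to_axis(frame: BasePairFrame, axis: np.ndarray) -> BasePairFrame:
    """Project a frame onto a helical axis (orientation only).

    The output z equals ``axis``; x is the normalized projection of the input x
    onto the plane normal to the axis; y completes the right-handed triad; the
    origin is unchanged.
    """
    axis = np.asarray(axis, dtype=float).reshape(3)
    axis = axis / np.linalg.norm(axis)
    triad = _project_triads(frame.triad, axis)
    return BasePairFrame(frame.origin.copy(), triad, pair_index=frame.pair_index,
                         snapshot_index=frame.snapshot_index)


def end_to_end_twist(
    frames: list[BasePairFrame], first: int, last: int
) -> GlobalTwist:
    """Global twist of one snapshot over the closed pair range [first, last].

    The end frames are the projections of pair frames ``first`` and ``last``
    onto their local helical axes; the raw mean-plane angle between them is
    unwrapped by adding the multiple of 360 degrees that brings it nearest the
    sum of local mean-plane twists over the range.  The helical-twist sum and
    mean helical rise over the same steps are returned as well.
    """
    n = len(frames)
    if not (2 <= first < last <= n - 1):
        raise GeometryError(
            f"range [{first}, {last}] must be interior to the duplex (1..{n})"
        )
    axis_a = local_helical_axis(frames, first)
    axis_b = local_helical_axis(frames, last)
    end_a = project_frame_to_axis(frames[first - 1], axis_a)
    end_b = project_frame_to_axis(frames[last - 1], axis_b)
    raw = mean_plane_twist(end_a, end_b)

    steps = [
        step_screw_axis(frames[i - 1], frames[i]) for i in range(first, last)
    ]
    local_sum = sum(s.local_twist for s in steps)
    k = round((local_sum - raw) / 360.0)
    twist = raw + 360.0 * k
    htwist_sum = sum(s.h_twist for s in steps)
    mean_hrise = float(np.mean([s.h_rise for s in steps]))
    return GlobalTwist(float(twist), float(htwist_sum), mean_hrise, first, last)


# ---------------------------------------------------------------------------
# vectorized trajectory path


def global_twist_series(traj: FrameTrajectory, first: int, last: int):
    """End-to-end twist, h-twist sum and mean h-rise for every snapshot.

    Vectorized equivalent of :func:`end_to_end_twist` applied per snapshot.
    Returns a pandas DataFrame with columns ``snapshot``,
    ``end_to_end_twist_deg``, ``htwist_sum_deg``, ``mean_hrise_A``.
    """
    import pandas as pd

    n = traj.n_bp
    if not (2 <= first < last <= n - 1):
        raise GeometryError(
            f"range [{first}, {last}] must be interior to the duplex (1..{n})"
        )
    R = traj.triads
    o = traj.origins
    h_twist, h_rise, axes = _batch_screw(R[:, :-1], R[:, 1:], o[:, :-1], o[:, 1:])
    # local mean-plane twists of all steps
    x = R[..., :, 0]
    z = R[..., :, 2]
    local = _mean_plane_angle(x[:, :-1], z[:, :-1], x[:, 1:], z[:, 1:])

    def _end_axis(p):  # 1-based pair index -> (S, 3) unit axes
        mean = axes[:, p - 2] + axes[:, p - 1]
        return mean / np.linalg.norm(mean, axis=-1, keepdims=True)

    tri_a = _project_triads(R[:, first - 1], _end_axis(first))
    tri_b = _project_triads(R[:, last - 1], _end_axis(last))
    raw = _mean_plane_angle(
        tri_a[..., :, 0], tri_a[..., :, 2], tri_b[..., :, 0], tri_b[..., :, 2]
    )
    sl = slice(first - 1, last - 1)  # steps within the range
    local_sum = local[:, sl].sum(axis=1)
    k = np.round((local_sum - raw) / 360.0)
    twist = raw + 360.0 * k
    return pd.DataFrame(
        {
            "snapshot": np.arange(traj.n_snapshots),
            "end_to_end_twist_deg": twist,
            "htwist_sum_deg": h_twist[:, sl].sum(axis=1),
            "mean_hrise_A": h_rise[:, sl].mean(axis=1),
        }
    )
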