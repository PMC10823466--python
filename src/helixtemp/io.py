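"""File formats: multi-model PDB, the 3DNA ``ref_frames.dat`` dialect, TSV
tables for tweezer traces and free-energy surfaces, and JSON truth sidecars.

PDB handling is delegated to biotite (one MODEL record per snapshot); the
frames file is a plain-text dialect — per snapshot a ``N base-pairs`` header,
then per pair a ``...  i  W-C  ...`` label line, an origin line, and three
rows holding the x-, y- and z-axis of the pair triad.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .frame_geometry import (
    BasePairFrame,
    FrameTrajectory,
    fit_base_frame,
    pair_midframe,
)
from .synthetic_data import DuplexAtoms, SyntheticTruth
from .templates import RES_NAME_TO_BASE

__all__ = [
    "write_pdb",
    "read_pdb",
    "write_frames_file",
    "read_frames_file",
    "frames_from_atoms",
    "write_truth",
    "read_truth",
    "write_trace_tsv",
    "read_trace_tsv",
]


def write_pdb(atoms: DuplexAtoms, path: str | Path) -> None:
    """Write an atom trajectory as a multi-model PDB (one MODEL per snapshot)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    S, n, _ = atoms.coords.shape
    stack = struc.AtomArrayStack(S, n)
    stack.coord = atoms.coords
    stack.set_annotation("chain_id", atoms.chain_ids.astype("U4"))
    stack.set_annotation("res_id", atoms.res_ids)
    stack.set_annotation("res_name", atoms.res_names.astype("U5"))
    stack.set_annotation("atom_name", atoms.atom_names.astype("U6"))
    stack.set_annotation(
        "element", np.array([a[0] for a in atoms.atom_names], dtype="U2")
    )
    stack.set_annotation("hetero", np.zeros(n, dtype=bool))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb(path: str | Path) -> DuplexAtoms:
    """Read a multi-model PDB written by :func:`write_pdb` (or equivalent)."""
    from biotite.structure.io.pdb import PDBFile

    stack = PDBFile.read(str(path)).get_structure(model=None)
    return DuplexAtoms(
        coords=np.asarray(stack.coord, dtype=float),
        atom_names=np.asarray(stack.atom_name),
        chain_ids=np.asarray(stack.chain_id),
        res_ids=np.asarray(stack.res_id, dtype=int),
        res_names=np.asarray(stack.res_name),
    )


def write_frames_file(traj: FrameTrajectory, path: str | Path) -> None:
    """Write per-snapshot base-pair frames in the ref_frames.dat dialect."""
    seq = traj.sequence or "N" * traj.n_bp
    lines: list[str] = []
    if traj.temperature is not None:
        lines.append(f"# temperature_C = {traj.temperature:g}")
    for s in range(traj.n_snapshots):
        lines.append(f"{traj.n_bp:>5d} base-pairs")
        for i in range(traj.n_bp):
            b = seq[i] if i < len(seq) else "N"
            lines.append(f"... {i + 1:>5d} {b}-{_wc_partner(b)} ...")
            o = traj.origins[s, i]
            lines.append(f"{o[0]:12.6f}{o[1]:12.6f}{o[2]:12.6f}")
            for ax in range(3):  # rows: x-, y-, z-axis
                v = traj.triads[s, i, :, ax]
                lines.append(f"{v[0]:12.6f}{v[1]:12.6f}{v[2]:12.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _wc_partner(base: str) -> str:
    return {"A": "U", "U": "A", "T": "A", "G": "C", "C": "G"}.get(base, "N")


def read_frames_file(path: str | Path) -> FrameTrajectory:
    """Read the frames-file dialect back into a :class:`FrameTrajectory`."""
    temperature = None
    snapshots: list[tuple[list, list]] = []
    origins: list[np.ndarray] = []
    triads: list[np.ndarray] = []
    sequence: list[str] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("#"):
            if "temperature_C" in ln:
                temperature = float(ln.split("=")[1])
            i += 1
            continue
        if "base-pairs" in ln:
            n_bp = int(ln.split()[0])
            o = np.empty((n_bp, 3))
            r = np.empty((n_bp, 3, 3))
            i += 1
            seq_chars = []
            for p in range(n_bp):
                label = lines[i]
                tok = [t for t in label.split() if "-" in t and len(t) == 3]
                seq_chars.append(tok[0][0] if tok else "N")
                o[p] = np.fromstring(lines[i + 1], sep=" ")
                rows = np.array(
                    [np.fromstring(lines[i + 2 + ax], sep=" ") for ax in range(3)]
                )
                r[p] = rows.T  # rows were the axes; columns of the triad
                i += 5
            origins.append(o)
            triads.append(r)
            if not sequence:
                sequence = seq_chars
        else:  # pragma: no cover - malformed line
            raise ValueError(f"unexpected line in frames file: {ln!r}")
    return FrameTrajectory(
        np.stack(origins), np.stack(triads),
        sequence="".join(sequence), temperature=temperature,
    )


def frames_from_atoms(atoms: DuplexAtoms) -> FrameTrajectory:
    """Fit base-pair frames to an atom trajectory.

    Per snapshot and pair, the standard-base template is superposed on each of
    the two bases and the two base frames are combined by
    :func:`~helixtemp.frame_geometry.pair_midframe`.
    """
    n_bp = atoms.n_bp
    S = atoms.n_snapshots
    origins = np.empty((S, n_bp, 3))
    triads = np.empty((S, n_bp, 3, 3))
    seq_chars = []

    groups: dict[tuple[str, int], np.ndarray] = {}
    for chain in ("A", "B"):
        mask_c = atoms.chain_ids == chain
        for rid in np.unique(atoms.res_ids[mask_c]):
            groups[(chain, int(rid))] = np.flatnonzero(
                mask_c & (atoms.res_ids == rid)
            )

    for i in range(1, n_bp + 1):
        idx_w = groups[("A", i)]
        idx_c = groups[("B", n_bp + 1 - i)]
        base_w = RES_NAME_TO_BASE[str(atoms.res_names[idx_w[0]])]
        base_c = RES_NAME_TO_BASE[str(atoms.res_names[idx_c[0]])]
        seq_chars.append(base_w)
        names_w = [str(n) for n in atoms.atom_names[idx_w]]
        names_c = [str(n) for n in atoms.atom_names[idx_c]]
        for s in range(S):
            fw = fit_base_frame(atoms.coords[s, idx_w], names_w, base_w)
            fc = fit_base_frame(atoms.coords[s, idx_c], names_c, base_c)
            mid = pair_midframe(fw, fc)
            origins[s, i - 1] = mid.origin
            triads[s, i - 1] = mid.triad
    return FrameTrajectory(origins, triads, sequence="".join(seq_chars))


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict()))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_trace_tsv(curves, path: str | Path) -> None:
    """Write rotation-extension traces as a tidy TSV
    (turns, extension_um, temperature_C, tether_id, replicate)."""
    rows = []
    for k, c in enumerate(curves):
        rows.append(
            pd.DataFrame(
                {
                    "turns": c.turns,
                    "extension_um": c.extension,
                    "temperature_C": c.temperature,
                    "tether_id": c.tether_id,
                    "replicate": getattr(c, "replicate", k),
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_trace_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
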