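"""Embedded standard-base geometry.

Idealized planar heavy-atom coordinates of the five canonical bases, expressed in
the standard base reference frame (origin near the pair center, x toward the major
groove, y toward the reference-strand backbone, z along the helix for the reference
strand).  In this convention an ideal Watson-Crick pair is formed when the
complementary base carries the same template after a 180-degree rotation about x
(y and z negated), which places the donor-acceptor heavy atoms 2.85-3.05 A apart.

Only base heavy atoms are stored (ring plus exocyclic WC donors/acceptors); sugars
and phosphates are not modelled.
"""

from __future__ import annotations

import numpy as np

#: 180-degree rotation about x used to express the complementary strand's base
#: frame in the pair frame (negates the y and z axes).
FLIP = np.diag([1.0, -1.0, -1.0])

# fmt: off
BASE_ATOMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498, 0.000), "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000), "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000), "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000), "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000), "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "N9": (-1.289, 4.551, 0.000), "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000), "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000), "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000), "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, 0.000), "N3": (-2.342, 2.364, 0.000),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "N1": (-1.285, 4.542, 0.000), "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.000), "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000), "N4": (1.875, 2.027, 0.000),
        "C5": (1.056, 4.275, 0.000), "C6": (-0.023, 5.068, 0.000),
    },
    "T": {
        "N1": (-1.284, 4.500, 0.000), "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000), "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000), "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000), "C7": (2.466, 4.961, 0.000),
        "C6": (-0.024, 5.057, 0.000),
    },
    "U": {
        "N1": (-1.284, 4.500, 0.000), "C2": (-1.462, 3.131, 0.000),
        "O2": (-2.563, 2.608, 0.000), "N3": (-0.302, 2.397, 0.000),
        "C4": (0.989, 2.884, 0.000), "O4": (1.935, 2.094, 0.000),
        "C5": (1.089, 4.311, 0.000), "C6": (-0.024, 5.053, 0.000),
    },
}
# fmt: on

#: Watson-Crick heavy-atom hydrogen bonds, keyed by (base, partner base) with
#: atom names (atom on first base, atom on partner).  A.T/A.U pairs carry two
#: bonds, G.C pairs three.
_WC_BONDS_CANONICAL: dict[tuple[str, str], list[tuple[str, str]]] = {
    ("A", "T"): [("N1", "N3"), ("N6", "O4")],
    ("A", "U"): [("N1", "N3"), ("N6", "O4")],
    ("G", "C"): [("O6", "N4"), ("N1", "N3"), ("N2", "O2")],
}

WC_BONDS: dict[tuple[str, str], list[tuple[str, str]]] = {}
for (_b1, _b2), _bonds in _WC_BONDS_CANONICAL.items():
    WC_BONDS[(_b1, _b2)] = list(_bonds)
    WC_BONDS[(_b2, _b1)] = [(a2, a1) for (a1, a2) in _bonds]

COMPLEMENT_RNA = {"A": "U", "U": "A", "G": "C", "C": "G", "T": "A"}
COMPLEMENT_DNA = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}

#: PDB residue names (modern convention: one-letter for ribo, D-prefixed for deoxy)
RES_NAME_RNA = {"A": "A", "U": "U", "G": "G", "C": "C"}
RES_NAME_DNA = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}
RES_NAME_TO_BASE = {
    "A": "A", "U": "U", "G": "G", "C": "C", "T": "T",
    "DA": "A", "DT": "T", "DG": "G", "DC": "C", "DU": "U",
    "RA": "A", "RU": "U", "RG": "G", "RC": "C",
}


def template_coords(base: str) -> tuple[list[str], np.ndarray]:
    """Atom names and (n, 3) template coordinates for one base identity."""
    try:
        atoms = BASE_ATOMS[base.upper()]
    except KeyError:
        raise ValueError(f"unknown base identity: {base!r}") from None
    names = list(atoms)
    return names, np.array([atoms[n] for n in names], dtype=float)


def complement(base: str, rna: bool = True) -> str:
    table = COMPLEMENT_RNA if rna else COMPLEMENT_DNA
    try:
        return table[base.upper()]
    except KeyError:
        raise ValueError(f"unknown base identity: {base!r}") from None
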