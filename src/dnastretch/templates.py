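"""Idealized per-base atom templates in the standard base-pair reference frame.

Heavy-atom base coordinates follow the standard nucleic-acid base reference
frame (x toward the major groove, y toward the strand-1 backbone, z along the
helical axis, all atoms of an undeformed base in the z = 0 plane).  A
Watson-Crick pair is formed by placing the complementary base with the 180°
rotation about x, i.e. (x, y, z) -> (x, -y, -z), which brings the canonical
donor/acceptor atoms to 2.8-3.1 Å separations.

Polar hydrogens are generated at 1.0 Å from their donor nitrogen along
idealized sp2 directions derived from the heavy-atom neighbours: ring N-H
along the exterior bisector of the two ring neighbours, amino N-H2 at ±60°
from the exterior C-N direction in the base plane.

The sugar-phosphate backbone is a simplified 11-atom set placed at plausible
B-DNA radii.  It exists so that stacking-energy sums, PDB output and the
terminal-atom force selection have realistic atom inventories; covalent
continuity between residues is not modelled (no bonded terms are computed
anywhere in this package).
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

PURINES = {"A", "G"}

#: glycosidic nitrogen per base (attachment point of the sugar)
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "T": "N1", "C": "N1"}

# Heavy-atom base templates: name -> (x, y) in the standard frame (z = 0).
_BASE_XY = {
    "A": {
        "N9": (-1.291, 4.498), "C8": (0.024, 4.897), "N7": (0.877, 3.902),
        "C5": (0.071, 2.771), "C6": (0.369, 1.398), "N6": (1.611, 0.909),
        "N1": (-0.668, 0.532), "C2": (-1.912, 1.023), "N3": (-2.320, 2.290),
        "C4": (-1.267, 3.124),
    },
    "G": {
        "N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
        "C5": (0.071, 2.833), "C6": (0.424, 1.460), "O6": (1.554, 0.955),
        "N1": (-0.700, 0.641), "C2": (-1.999, 1.087), "N2": (-2.949, 0.139),
        "N3": (-2.342, 2.364), "C4": (-1.265, 3.177),
    },
    "T": {
        "N1": (-1.284, 4.500), "C2": (-1.462, 3.135), "O2": (-2.562, 2.608),
        "N3": (-0.298, 2.407), "C4": (0.994, 2.897), "O4": (1.944, 2.119),
        "C5": (1.106, 4.338), "C7": (2.466, 4.961), "C6": (-0.024, 5.057),
    },
    "C": {
        "N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "O2": (-2.628, 2.709),
        "N3": (-0.391, 2.344), "C4": (0.837, 2.868), "N4": (1.875, 2.027),
        "C5": (1.056, 4.275), "C6": (-0.023, 5.068),
    },
}

#: H-bond donor heavy atoms (all nitrogens carrying polar hydrogens)
DONORS = {"A": ("N6",), "T": ("N3",), "G": ("N1", "N2"), "C": ("N4",)}

#: H-bond acceptor heavy atoms on the base moiety
ACCEPTORS = {
    "A": ("N1", "N3", "N7"),
    "T": ("O2", "O4"),
    "G": ("O6", "N3", "N7"),
    "C": ("O2", "N3"),
}

# donor heavy atom -> its ring/amino neighbours used to build H directions;
# a single neighbour marks an amino group (two hydrogens at ±60°).
_DONOR_NEIGHBOURS = {
    ("A", "N6"): ("C6",),
    ("T", "N3"): ("C2", "C4"),
    ("G", "N1"): ("C2", "C6"),
    ("G", "N2"): ("C2",),
    ("C", "N4"): ("C4",),
}

_NH_BOND = 1.0  # Å, idealized N-H length

# Simplified backbone template, shared by all four bases: name -> (x, y, z).
# C1' sits 1.46 Å from the glycosidic nitrogen; P at ~10 Å radius so that the
# successive-residue P...P distance is ~7 Å at 36°/3.3 Å helical steps.
BACKBONE_XYZ = {
    "C1'": (-2.477, 5.399, 0.000),
    "C2'": (-1.600, 6.630, 0.300),
    "O4'": (-3.700, 6.110, -0.200),
    "C3'": (-2.600, 7.730, 0.550),
    "O3'": (-2.400, 8.600, 1.650),
    "C4'": (-3.900, 7.100, 0.850),
    "C5'": (-5.050, 7.600, 0.050),
    "O5'": (-5.500, 8.100, -1.200),
    "P": (-6.100, 8.000, -2.600),
    "OP1": (-7.400, 8.600, -2.400),
    "OP2": (-5.300, 8.800, -3.550),
}

#: Watson-Crick canonical H-bond atom pairs, keyed by (purine, pyrimidine);
#: each entry is (purine atom, pyrimidine atom).
WC_HBOND_ATOMS = {
    ("A", "T"): (("N6", "O4"), ("N1", "N3")),
    ("G", "C"): (("O6", "N4"), ("N1", "N3"), ("N2", "O2")),
}


def _rot2(v: np.ndarray, degrees: float) -> np.ndarray:
    a = np.deg2rad(degrees)
    c, s = np.cos(a), np.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _hydrogen_positions(base: str) -> dict[str, np.ndarray]:
    """Polar hydrogen template coordinates (z = 0 plane) for one base."""
    xy = _BASE_XY[base]
    out: dict[str, np.ndarray] = {}
    for (b, donor), neighbours in _DONOR_NEIGHBOURS.items():
        if b != base:
            continue
        d = np.asarray(xy[donor], dtype=float)
        if len(neighbours) == 2:  # ring N-H: exterior bisector
            mid = 0.5 * (np.asarray(xy[neighbours[0]]) + np.asarray(xy[neighbours[1]]))
            u = d - mid
            u /= np.linalg.norm(u)
            name = "H3" if donor == "N3" else "H1"
            out[name] = d + _NH_BOND * u
        else:  # amino N-H2: ±60° off the exterior C->N direction
            u = d - np.asarray(xy[neighbours[0]])
            u /= np.linalg.norm(u)
            num = donor[1]  # N6 -> H61/H62 etc.
            out[f"H{num}1"] = d + _NH_BOND * _rot2(u, +60.0)
            out[f"H{num}2"] = d + _NH_BOND * _rot2(u, -60.0)
    return out


def _build_template(base: str):
    """(names, elements, roles, coords) arrays for one nucleotide template."""
    names: list[str] = []
    elements: list[str] = []
    roles: list[str] = []
    coords: list[tuple[float, float, float]] = []

    donors = set(DONORS[base])
    acceptors = set(ACCEPTORS[base])
    for name, (x, y) in _BASE_XY[base].items():
        if name in donors:
            role = "base-donor"
        elif name in acceptors:
            role = "base-acceptor"
        else:
            role = "base-other"
        names.append(name)
        elements.append(name[0])
        roles.append(role)
        coords.append((x, y, 0.0))
    for name, pos in _hydrogen_positions(base).items():
        names.append(name)
        elements.append("H")
        roles.append("base-hydrogen")
        coords.append((pos[0], pos[1], 0.0))
    for name, xyz in BACKBONE_XYZ.items():
        names.append(name)
        elements.append(name[0] if name != "OP1" and name != "OP2" else "O")
        roles.append("backbone")
        coords.append(xyz)
    return (
        tuple(names),
        tuple(elements),
        tuple(roles),
        np.asarray(coords, dtype=float),
    )


#: base letter -> (atom names, elements, roles, template coordinates)
NUCLEOTIDE_TEMPLATES = {b: _build_template(b) for b in "ATGC"}

#: donor heavy atom -> names of its attached hydrogens, per base
DONOR_HYDROGENS = {
    ("A", "N6"): ("H61", "H62"),
    ("T", "N3"): ("H3",),
    ("G", "N1"): ("H1",),
    ("G", "N2"): ("H21", "H22"),
    ("C", "N4"): ("H41", "H42"),
}

#: base atoms used to define the base plane normal (first three, noncollinear)
BASE_FRAME_ATOMS = {
    "A": ("N9", "N1", "C6"),
    "G": ("N9", "N1", "C6"),
    "T": ("N1", "N3", "C4"),
    "C": ("N1", "N3", "C4"),
}


def reverse_complement(sequence: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(sequence))
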