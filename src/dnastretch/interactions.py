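"""Hydrogen-bond detection/classification and the stacking-energy partition.

Hydrogen bonds use the geometric criterion common to trajectory-analysis
tools: donor-heavy-atom to acceptor-heavy-atom distance <= 3.5 Å and
donor-H...acceptor angle >= 120°, both boundaries inclusive.  A bond is
canonical when it joins one of the Watson-Crick donor/acceptor atom pairs
(A·T: N6-O4, N1-N3; G·C: O6-N4, N1-N3, N2-O2) between WC-paired residues;
every other base-base bond is non-canonical.  Bonds are assigned to the base
pair of their donor residue.

Stacking energies are 12-6 Lennard-Jones sums over all inter-residue atom
pairs, split per nucleotide into a canonical channel (intra-strand
successive neighbours, i.e. true stacking) and a non-canonical channel
(every other residue, including the inter-strand diagonal "cross-stacking"
partners).  The nucleotide itself and its WC partner are excluded from both
channels.  The 5-class LJ table ships representative biomolecular-forcefield
parameters and is editable; absolute values are approximations, so every
energy threshold downstream is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .duplex import Duplex
from .templates import DONOR_HYDROGENS, PURINES, WC_HBOND_ATOMS


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond cutoffs (inclusive boundaries)."""

    max_distance: float = 3.5  # Å, donor heavy atom to acceptor heavy atom
    min_angle: float = 120.0  # degrees, donor-H...acceptor

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if not 0.0 <= self.min_angle <= 180.0:
            raise ValueError("min_angle must be within [0, 180] degrees")


@dataclass(frozen=True)
class HBond:
    donor: str  # "strand:resindex:atom"
    hydrogen: str
    acceptor: str
    distance: float
    angle: float
    hbond_class: str  # "canonical" | "non-canonical"
    bp_assignment: int


# Representative 12-6 parameters per element class; rmin_half in Å, epsilon
# in kcal/mol.  Pair rules: rmin_ij = rmin_half_i + rmin_half_j (arithmetic),
# eps_ij = sqrt(eps_i * eps_j) (geometric).
_DEFAULT_LJ = {
    "C": (0.0860, 1.908),
    "N": (0.1700, 1.824),
    "O": (0.2100, 1.661),
    "P": (0.2000, 2.100),
    "H": (0.0157, 0.600),
}


@dataclass(frozen=True)
class LJTable:
    """Per-element-class Lennard-Jones well depths and minimum radii."""

    epsilon: dict = field(default_factory=lambda: {k: v[0] for k, v in _DEFAULT_LJ.items()})
    rmin_half: dict = field(default_factory=lambda: {k: v[1] for k, v in _DEFAULT_LJ.items()})

    def __post_init__(self):
        for k, e in self.epsilon.items():
            if e <= 0 or self.rmin_half.get(k, 0) <= 0:
                raise ValueError(f"epsilon and rmin must be positive for class {k}")

    def pair_params(self, el_a: str, el_b: str) -> tuple[float, float]:
        """(eps_ij, rmin_ij) for an element pair."""
        for el in (el_a, el_b):
            if el not in self.epsilon:
                raise KeyError(f"unknown element {el!r} in LJ table")
        eps = float(np.sqrt(self.epsilon[el_a] * self.epsilon[el_b]))
        rmin = self.rmin_half[el_a] + self.rmin_half[el_b]
        return eps, rmin

    def pair_energy(self, el_a: str, el_b: str, r: float) -> float:
        eps, rmin = self.pair_params(el_a, el_b)
        sr6 = (rmin / r) ** 6
        return eps * (sr6 * sr6 - 2.0 * sr6)


@dataclass
class StackingRecord:
    """Per-nucleotide stacking partition, kcal/mol."""

    strand: int
    index: int
    canonical_energy: float
    noncanonical_energy: float


class FrameAnalyzer:
    """Vectorized per-frame interaction analysis bound to one duplex topology.

    Precomputes donor/hydrogen/acceptor index triples, residue membership
    and LJ pair parameters once, then evaluates frames (flat coordinate
    arrays in the duplex's atom order) cheaply.
    """

    def __init__(self, duplex: Duplex, criteria: HBondCriteria | None = None,
                 lj: LJTable | None = None):
        self.duplex = duplex
        self.criteria = criteria or HBondCriteria()
        self.lj = lj or LJTable()
        table = duplex.atom_table()
        self.table = table
        n = duplex.n_bp

        # residue bookkeeping: flat residue id per atom
        res_key = list(zip(table["strand"], table["residue_index"]))
        self._res_ids = sorted(set(res_key))
        rid_of = {k: i for i, k in enumerate(self._res_ids)}
        self._atom_rid = np.array([rid_of[k] for k in res_key])
        self._res_strand = np.array([k[0] for k in self._res_ids])
        self._res_index = np.array([k[1] for k in self._res_ids])
        self._res_bp = np.where(self._res_strand == 1, self._res_index,
                                n + 1 - self._res_index)
        self._res_base = {}
        for nt in duplex.nucleotides:
            self._res_base[rid_of[(nt.strand, nt.index)]] = nt.base

        names = table["name"].to_numpy()
        roles = table["role"].to_numpy()
        bases = table["base"].to_numpy()

        # donor / hydrogen / acceptor index triples
        donors, hydros = [], []
        idx_by_res_name = {}
        for i, (rid, nm) in enumerate(zip(self._atom_rid, names)):
            idx_by_res_name[(rid, nm)] = i
        for i in np.flatnonzero(roles == "base-donor"):
            rid = self._atom_rid[i]
            hyd_names = DONOR_HYDROGENS.get((bases[i], names[i]))
            if not hyd_names:
                raise ValueError(
                    f"donor atom {names[i]} of base {bases[i]} has no attached "
                    f"hydrogen in the template table"
                )
            for h in hyd_names:
                j = idx_by_res_name.get((rid, h))
                if j is None:
                    raise ValueError(
                        f"donor {names[i]} (residue {self._res_ids[rid]}) is "
                        f"missing its hydrogen {h}"
                    )
                donors.append(i)
                hydros.append(j)
        self._don = np.asarray(donors, dtype=int)
        self._hyd = np.asarray(hydros, dtype=int)
        self._acc = np.flatnonzero(roles == "base-acceptor")
        self._names = names

        # LJ pair parameter matrices over all atoms
        els = table["element"].to_numpy()
        eps1 = np.array([self.lj.epsilon[e] if e in self.lj.epsilon else np.nan
                         for e in els])
        if np.any(np.isnan(eps1)):
            bad = els[np.isnan(eps1)][0]
            raise KeyError(f"unknown element {bad!r} in LJ table")
        rm1 = np.array([self.lj.rmin_half[e] for e in els])
        self._eps = np.sqrt(np.outer(eps1, eps1))
        self._rmin2 = (rm1[:, None] + rm1[None, :]) ** 2

        # residue indicator matrix for summing atom energies into residues
        n_res = len(self._res_ids)
        self._R = np.zeros((len(table), n_res))
        self._R[np.arange(len(table)), self._atom_rid] = 1.0

        # residue-pair channel masks
        partner = {}
        for i in range(1, n + 1):
            a = rid_of[(1, i)]
            b = rid_of[(2, n + 1 - i)]
            partner[a], partner[b] = b, a
        self._partner = partner
        same_strand = self._res_strand[:, None] == self._res_strand[None, :]
        succ = np.abs(self._res_index[:, None] - self._res_index[None, :]) == 1
        self._canon_mask = same_strand & succ
        part_mask = np.zeros((n_res, n_res), dtype=bool)
        for a, b in partner.items():
            part_mask[a, b] = True
        eye = np.eye(n_res, dtype=bool)
        self._noncanon_mask = ~(self._canon_mask | part_mask | eye)

    # -- hydrogen bonds -------------------------------------------------------

    def detect_hbonds(self, coords: np.ndarray) -> list[HBond]:
        """All base-base H-bonds in one frame, classified and bp-assigned."""
        crit = self.criteria
        D = coords[self._don]  # (nd, 3)
        H = coords[self._hyd]
        A = coords[self._acc]  # (na, 3)
        # distance: donor heavy atom to acceptor heavy atom
        dvec = A[None, :, :] - D[:, None, :]
        dist = np.linalg.norm(dvec, axis=2)
        # angle at H between H->D and H->A
        hd = D - H
        ha = A[None, :, :] - H[:, None, :]
        num = np.einsum("ij,ikj->ik", hd, ha)
        den = np.linalg.norm(hd, axis=1)[:, None] * np.linalg.norm(ha, axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            ang = np.rad2deg(np.arccos(np.clip(num / den, -1.0, 1.0)))
        same_res = (self._atom_rid[self._don][:, None]
                    == self._atom_rid[self._acc][None, :])
        hits = (dist <= crit.max_distance) & (ang >= crit.min_angle) & ~same_res
        out: list[HBond] = []
        for di, ai in zip(*np.nonzero(hits)):
            d_idx, h_idx, a_idx = self._don[di], self._hyd[di], self._acc[ai]
            rd, ra = self._atom_rid[d_idx], self._atom_rid[a_idx]
            cls = ("canonical"
                   if self._is_canonical(rd, self._names[d_idx], ra,
                                          self._names[a_idx])
                   else "non-canonical")
            out.append(HBond(
                donor=self._atom_label(d_idx),
                hydrogen=self._atom_label(h_idx),
                acceptor=self._atom_label(a_idx),
                distance=float(dist[di, ai]),
                angle=float(ang[di, ai]),
                hbond_class=cls,
                bp_assignment=int(self._res_bp[rd]),
            ))
        return out

    def _atom_label(self, i: int) -> str:
        rid = self._atom_rid[i]
        s, r = self._res_ids[rid]
        return f"{s}:{r}:{self._names[i]}"

    def _is_canonical(self, rid_d: int, name_d: str, rid_a: int, name_a: str) -> bool:
        if self._partner.get(rid_d) != rid_a:
            return False
        bd, ba = self._res_base[rid_d], self._res_base[rid_a]
        if bd in PURINES:
            key, pair = (bd, ba), (name_d, name_a)
        else:
            key, pair = (ba, bd), (name_a, name_d)
        return pair in WC_HBOND_ATOMS.get(key, ())

    def classify_hbonds(self, hbonds: list[HBond]) -> tuple[np.ndarray, np.ndarray]:
        """Per-bp (canonical, non-canonical) bond counts, index 0 = bp 1."""
        n = self.duplex.n_bp
        canon = np.zeros(n)
        noncanon = np.zeros(n)
        for hb in hbonds:
            i = hb.bp_assignment - 1
            if hb.hbond_class == "canonical":
                canon[i] += 1
            else:
                noncanon[i] += 1
        return canon, noncanon

    # -- stacking -------------------------------------------------------------

    def residue_pair_energies(self, coords: np.ndarray) -> np.ndarray:
        """Symmetric residue-by-residue LJ energy matrix (kcal/mol)."""
        from scipy.spatial.distance import cdist

        d2 = cdist(coords, coords, "sqeuclidean")
        np.fill_diagonal(d2, np.inf)
        sr6 = self._rmin2 / d2
        sr6 **= 3
        e_atom = self._eps * (sr6 * sr6 - 2.0 * sr6)
        return self._R.T @ e_atom @ self._R

    def stacking_energies(self, coords: np.ndarray) -> list[StackingRecord]:
        """Per-nucleotide canonical/non-canonical stacking partition."""
        e_res = self.residue_pair_energies(coords)
        canon = np.sum(e_res * self._canon_mask, axis=1)
        noncanon = np.sum(e_res * self._noncanon_mask, axis=1)
        return [
            StackingRecord(int(s), int(i), float(c), float(nc))
            for (s, i), c, nc in zip(self._res_ids, canon, noncanon)
        ]

    def per_bp_channels(self, coords: np.ndarray) -> dict[str, np.ndarray]:
        """All four per-bp channels for one frame.

        Stacking channels per bp are the sum over the pair's two
        nucleotides (each residue-pair energy is credited to both of its
        participants).
        """
        canon_hb, noncanon_hb = self.classify_hbonds(self.detect_hbonds(coords))
        e_res = self.residue_pair_energies(coords)
        canon_nt = np.sum(e_res * self._canon_mask, axis=1)
        noncanon_nt = np.sum(e_res * self._noncanon_mask, axis=1)
        n = self.duplex.n_bp
        canon_stack = np.zeros(n)
        noncanon_stack = np.zeros(n)
        np.add.at(canon_stack, self._res_bp - 1, canon_nt)
        np.add.at(noncanon_stack, self._res_bp - 1, noncanon_nt)
        return {
            "canonical_hb": canon_hb,
            "noncanonical_hb": noncanon_hb,
            "canonical_stack": canon_stack,
            "noncanonical_stack": noncanon_stack,
        }


# -- thin functional wrappers matching the module surface ---------------------

def detect_hbonds(duplex: Duplex, coords: np.ndarray | None = None,
                  criteria: HBondCriteria | None = None) -> list[HBond]:
    ana = FrameAnalyzer(duplex, criteria=criteria)
    return ana.detect_hbonds(coords if coords is not None else duplex.coordinates())


def classify_hbonds(duplex: Duplex, hbonds: list[HBond]) -> tuple[np.ndarray, np.ndarray]:
    return FrameAnalyzer(duplex).classify_hbonds(hbonds)


def stacking_energies(duplex: Duplex, coords: np.ndarray | None = None,
                      lj: LJTable | None = None) -> list[StackingRecord]:
    ana = FrameAnalyzer(duplex, lj=lj)
    return ana.stacking_energies(coords if coords is not None else duplex.coordinates())
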