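"""Idealized B-DNA duplex construction, supercoiling, and step parameters.

A duplex is built from planar base templates stacked along the +z helical
axis: base pair ``i`` (1-based) is the standard pair frame rotated by
``(i-1)*twist0`` about z and translated to ``z = (i-1)*rise0``.  Strand 1
runs 5'->3' with ascending z; strand 2 is its reverse complement, placed by
the 180° x-axis flip of the pair frame.  Right-handed twist is positive.

Supercoiling density is defined relative to the relaxed linking number,
sigma = (Lk - Lk0) / Lk0, with the convention Lk0 = (n_bp - 1) * twist0/360
(the summed relaxed step twist in turns).  Imposing sigma rotates the
terminal base pair about z by sigma*Lk0*360° and distributes the added twist
uniformly over all steps, standing in for torsional relaxation; sigma < 0
(under-twist) reduces the per-step twist.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .templates import (
    BASE_FRAME_ATOMS,
    COMPLEMENT,
    NUCLEOTIDE_TEMPLATES,
    reverse_complement,
)

DEFAULT_TWIST0 = 36.0  # degrees per bp step (canonical B-DNA)
DEFAULT_RISE0 = 3.3  # Å per bp step


@dataclass(frozen=True)
class Atom:
    """One atom record: PDB-style name, element, role, position in Å."""

    name: str
    element: str
    position: np.ndarray
    role: str

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")


@dataclass
class Nucleotide:
    """One nucleotide: 1-based index along its strand, strand 1 or 2."""

    index: int
    strand: int
    base: str
    atoms: list[Atom]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name} not in {self.base}{self.index} strand {self.strand}")


@dataclass(frozen=True)
class HelicalParams:
    """Uniform helical geometry: twist (deg/step), rise (Å/step), bp count."""

    twist0: float = DEFAULT_TWIST0
    rise0: float = DEFAULT_RISE0
    n_bp: int = 24

    def __post_init__(self):
        if not 0.0 < self.twist0 < 60.0:
            raise ValueError(f"twist0 must be in (0, 60) degrees, got {self.twist0}")
        if not 2.0 < self.rise0 < 5.0:
            raise ValueError(f"rise0 must be in (2, 5) Å, got {self.rise0}")
        if self.n_bp < 1:
            raise ValueError(f"n_bp must be >= 1, got {self.n_bp}")

    @property
    def lk0(self) -> float:
        """Relaxed linking number convention: summed step twist in turns."""
        return (self.n_bp - 1) * self.twist0 / 360.0


@dataclass(frozen=True)
class SupercoilState:
    """Linking-number bookkeeping: sigma = delta_lk / lk0 exactly."""

    lk0: float
    delta_lk: float
    sigma: float

    def __post_init__(self):
        if self.lk0 <= 0:
            raise ValueError("lk0 must be positive")
        if self.sigma != self.delta_lk / self.lk0:
            raise ValueError("sigma must equal delta_lk / lk0 exactly")

    @classmethod
    def from_delta(cls, delta_lk: float, lk0: float) -> "SupercoilState":
        return cls(lk0=lk0, delta_lk=delta_lk, sigma=delta_lk / lk0)


@dataclass
class Duplex:
    """All-atom idealized duplex with WC pairing map.

    ``nucleotides`` holds strand 1 (indices 1..N, ascending z) followed by
    strand 2 (indices 1..N in its own 5'->3' order, descending z).  Base pair
    ``i`` pairs strand-1 residue ``i`` with strand-2 residue ``N+1-i``.
    """

    sequence: str
    nucleotides: list[Nucleotide]
    helical_params: HelicalParams
    supercoil: SupercoilState = field(default=None)

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @property
    def pairing(self) -> dict[int, int]:
        n = self.n_bp
        return {i: n + 1 - i for i in range(1, n + 1)}

    def strand(self, which: int) -> list[Nucleotide]:
        return [nt for nt in self.nucleotides if nt.strand == which]

    def nucleotide(self, strand: int, index: int) -> Nucleotide:
        off = 0 if strand == 1 else self.n_bp
        nt = self.nucleotides[off + index - 1]
        assert nt.strand == strand and nt.index == index
        return nt

    def pair(self, bp: int) -> tuple[Nucleotide, Nucleotide]:
        return self.nucleotide(1, bp), self.nucleotide(2, self.n_bp + 1 - bp)

    # -- flat coordinate view -------------------------------------------------
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array in nucleotide-then-atom order."""
        return np.concatenate([
            np.stack([a.position for a in nt.atoms]) for nt in self.nucleotides
        ])

    def with_coordinates(self, coords: np.ndarray) -> "Duplex":
        """Copy of this duplex with atom positions replaced from a flat array."""
        new = copy.deepcopy(self)
        k = 0
        for nt in new.nucleotides:
            for j, a in enumerate(nt.atoms):
                nt.atoms[j] = Atom(a.name, a.element, coords[k].copy(), a.role)
                k += 1
        if k != len(coords):
            raise ValueError(f"coordinate count {len(coords)} != atom count {k}")
        return new

    def atom_table(self):
        """Flat per-atom metadata aligned with :meth:`coordinates` order."""
        import pandas as pd

        rows = []
        serial = 1
        for nt in self.nucleotides:
            bp = nt.index if nt.strand == 1 else self.n_bp + 1 - nt.index
            for a in nt.atoms:
                rows.append(
                    (serial, a.name, a.element, a.role, nt.strand, nt.index,
                     nt.base, bp, bp in (1, self.n_bp))
                )
                serial += 1
        return pd.DataFrame(
            rows,
            columns=["serial", "name", "element", "role", "strand",
                     "residue_index", "base", "bp", "terminal"],
        )


def _pair_frame_transform(coords: np.ndarray, twist_deg: float, z: float) -> np.ndarray:
    a = np.deg2rad(twist_deg)
    c, s = np.cos(a), np.sin(a)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    out = coords @ rot.T
    out[:, 2] += z
    return out


def build_duplex(sequence: str, params: HelicalParams | None = None) -> Duplex:
    """Construct an undeformed idealized duplex for a strand-1 sequence.

    Raises ``ValueError`` naming the first invalid character position if the
    sequence is not over {A, T, G, C}.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    sequence = sequence.upper()
    for pos, ch in enumerate(sequence, start=1):
        if ch not in COMPLEMENT:
            raise ValueError(
                f"invalid base {ch!r} at position {pos}; alphabet is A, T, G, C"
            )
    params = params or HelicalParams(n_bp=len(sequence))
    if params.n_bp != len(sequence):
        params = HelicalParams(params.twist0, params.rise0, len(sequence))

    n = len(sequence)
    flip = np.diag([1.0, -1.0, -1.0])  # WC partner placement: 180° about x

    strand1: list[Nucleotide] = []
    strand2: list[Nucleotide] = [None] * n
    for i, base in enumerate(sequence, start=1):
        twist = (i - 1) * params.twist0
        z = (i - 1) * params.rise0
        names, elements, roles, tmpl = NUCLEOTIDE_TEMPLATES[base]
        pos1 = _pair_frame_transform(tmpl.copy(), twist, z)
        strand1.append(
            Nucleotide(i, 1, base, [
                Atom(nm, el, p, rl)
                for nm, el, rl, p in zip(names, elements, roles, pos1)
            ])
        )
        comp = COMPLEMENT[base]
        names2, elements2, roles2, tmpl2 = NUCLEOTIDE_TEMPLATES[comp]
        pos2 = _pair_frame_transform(tmpl2 @ flip.T, twist, z)
        # strand-2 residue index: antiparallel partner of bp i is N+1-i
        strand2[n - i] = Nucleotide(n + 1 - i, 2, comp, [
            Atom(nm, el, p, rl)
            for nm, el, rl, p in zip(names2, elements2, roles2, pos2)
        ])
    return Duplex(sequence=sequence, nucleotides=strand1 + strand2,
                  helical_params=params)


def compute_sigma(delta_lk: float, lk0: float) -> float:
    """Supercoiling density sigma = (Lk - Lk0)/Lk0 = delta_lk/lk0."""
    if lk0 <= 0:
        raise ValueError(f"lk0 must be positive, got {lk0}")
    return delta_lk / lk0


def impose_supercoiling(duplex: Duplex, sigma_target: float,
                        lk0: float | None = None) -> Duplex:
    """Return a supercoiled copy of ``duplex``.

    The terminal base pair is rotated about the helical axis by
    ``sigma_target * lk0 * 360°`` and the added twist is distributed
    uniformly over all base-pair steps (a stand-in for torsional
    relaxation).  ``lk0`` defaults to the duplex's own convention,
    ``(n_bp-1)*twist0/360``; the rotation angle per unit sigma depends on
    this choice, so it is exposed for callers using another convention.

    Calls compose: imposing +sigma then -sigma restores the coordinates.
    """
    if abs(sigma_target) > 0.2:
        raise ValueError(f"|sigma| must be <= 0.2, got {sigma_target}")
    if lk0 is None:
        lk0 = duplex.helical_params.lk0
    n = duplex.n_bp
    delta_lk = sigma_target * lk0
    total_deg = delta_lk * 360.0
    coords = duplex.coordinates()
    if n > 1:
        table = duplex.atom_table()
        per_step = total_deg / (n - 1)
        for bp in range(1, n + 1):
            extra = (bp - 1) * per_step
            mask = (table["bp"] == bp).to_numpy()
            coords[mask] = _pair_frame_transform(coords[mask], extra, 0.0)
    new = duplex.with_coordinates(coords)
    prev = duplex.supercoil.delta_lk if duplex.supercoil else 0.0
    new.supercoil = SupercoilState.from_delta(prev + delta_lk, lk0)
    return new


@dataclass(frozen=True)
class StepParameters:
    """Per-step geometry; ``measurable`` is False if template atoms missing."""

    step: int  # between bp step and step+1 (1-based)
    twist: float  # degrees
    rise: float  # Å
    inclination: float  # degrees, mean base-normal tilt from the z axis
    measurable: bool = True


def _bp_geometry(duplex: Duplex, coords_by_atom: dict, bp: int):
    """Pair long-axis vector (C1'-C1'), centre, and mean base normal."""
    nt1, nt2 = duplex.pair(bp)
    try:
        c1 = coords_by_atom[(nt1.strand, nt1.index, "C1'")]
        c2 = coords_by_atom[(nt2.strand, nt2.index, "C1'")]
        normals = []
        for nt in (nt1, nt2):
            a, b, c = BASE_FRAME_ATOMS[nt.base]
            p = [coords_by_atom[(nt.strand, nt.index, x)] for x in (a, b, c)]
            nrm = np.cross(p[1] - p[0], p[2] - p[0])
            nrm /= np.linalg.norm(nrm)
            normals.append(nrm if nrm[2] >= 0 else -nrm)
    except KeyError as exc:
        raise KeyError(str(exc))
    axis = c1 - c2
    centre = 0.5 * (c1 + c2)
    return axis, centre, normals


def measure_step_parameters(duplex: Duplex,
                            coords: np.ndarray | None = None) -> list[StepParameters]:
    """Measure twist/rise/inclination for every bp step of a frame.

    Twist is the signed angle about z between successive pair long axes
    (C1'->C1' vectors projected on the xy plane); rise is the axial
    centre-to-centre displacement; inclination is the mean angle between the
    base-plane normals and the helical (z) axis.  A step whose pairs lack
    template atoms is flagged unmeasurable rather than skipped.
    """
    if duplex.n_bp < 2:
        raise ValueError("need at least 2 bp to measure step parameters")
    work = duplex if coords is None else duplex.with_coordinates(coords)
    coords_by_atom = {
        (nt.strand, nt.index, a.name): a.position
        for nt in work.nucleotides for a in nt.atoms
    }
    geoms = []
    for bp in range(1, work.n_bp + 1):
        try:
            geoms.append(_bp_geometry(work, coords_by_atom, bp))
        except KeyError:
            geoms.append(None)
    out: list[StepParameters] = []
    for step in range(1, work.n_bp):
        g0, g1 = geoms[step - 1], geoms[step]
        if g0 is None or g1 is None:
            out.append(StepParameters(step, np.nan, np.nan, np.nan, False))
            continue
        (ax0, c0, n0), (ax1, c1, n1) = g0, g1
        a0 = np.arctan2(ax0[1], ax0[0])
        a1 = np.arctan2(ax1[1], ax1[0])
        twist = np.rad2deg(np.angle(np.exp(1j * (a1 - a0))))
        rise = c1[2] - c0[2]
        normals = n0 + n1
        incl = float(np.mean([
            np.rad2deg(np.arccos(np.clip(abs(nrm[2]) / np.linalg.norm(nrm), -1, 1)))
            for nrm in normals
        ]))
        out.append(StepParameters(step, float(twist), float(rise), incl, True))
    return out


def sigma_from_steps(steps: list[StepParameters], params: HelicalParams) -> float:
    """Infer sigma from summed measured step twists against the Lk0 convention."""
    lk = sum(s.twist for s in steps if s.measurable) / 360.0
    return compute_sigma(lk - params.lk0, params.lk0)
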