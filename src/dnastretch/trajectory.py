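"""Seeded synthetic stretching trajectories and the study design matrix.

The generator emulates the umbrella-window stretching protocol: one terminal
base pair is displaced along the helical axis in fixed increments (1 Å per
window by default, 30 windows), the interior base pairs follow by linear
interpolation in z, and thermal motion is a per-atom Gaussian jitter.  Both
terminal base pairs are treated as rigidly trapped: their atoms are noise-free
and identical across the frames of a window.

Structural events seen in stretched, torsionally constrained DNA are injected
deterministically rather than emerging from dynamics:

* melting bubbles — both bases of the affected pairs swing in-plane away from
  the Watson-Crick geometry (rotation about a vertical axis through each
  C1', scaled by ``severity`` up to full disruption);
* non-canonical H-bond motifs — the strand-1 base shifts in-plane across the
  helix, past its partner, into a register where its donors and acceptors
  meet the partner's non-Watson-Crick atoms (shifted-partner contacts that
  the classifier reports as non-canonical);
* non-canonical stacking motifs — a smaller in-plane shift toward strand 2
  that keeps the WC bonds intact while strengthening the inter-strand
  diagonal (cross-stacking) vdW contacts.

Window duration (500 ps), stretch rate (2 Å/ns) and trap constant
(500 kcal/mol/Å²) are carried as metadata only; there is no integrator.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np

from .duplex import Duplex
from .force import ForceFrames

#: the four studied 24-bp homopolymer/alternating duplexes, strand-1 5'->3'
STUDY_SEQUENCES = {
    "(AA)12": "A" * 24,
    "(AT)12": "AT" * 12,
    "(CC)12": "C" * 24,
    "(CG)12": "CG" * 12,
}

#: supercoiling density grid used throughout the study
SIGMA_GRID = (-0.068, -0.051, -0.034, -0.017, 0.0, 0.017, 0.034, 0.051, 0.068)

#: salt labels, mM (metadata only; no electrostatics are computed)
SALT_LABELS = (50, 200)


@dataclass(frozen=True)
class StretchProtocol:
    """Umbrella-window stretching schedule."""

    step_size: float = 1.0  # Å per window
    n_steps: int = 30  # windows
    frames_per_window: int = 25
    window_time: float = 500.0  # ps, metadata
    trap_constant: float = 500.0  # kcal/mol/Å², metadata

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.frames_per_window < 1:
            raise ValueError("frames_per_window must be >= 1")


@dataclass(frozen=True)
class BubbleSpec:
    bp_start: int
    bp_end: int
    onset_window: int
    severity: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must be in [0, 1]")
        if self.bp_end < self.bp_start:
            raise ValueError("bp_end must be >= bp_start")


@dataclass(frozen=True)
class MotifSpec:
    bp_start: int
    bp_end: int
    onset_window: int
    mode: str  # "non-canonical-stacking" | "non-canonical-hbond"

    def __post_init__(self):
        if self.mode not in ("non-canonical-stacking", "non-canonical-hbond"):
            raise ValueError(f"unknown motif mode {self.mode!r}")
        if self.bp_end < self.bp_start:
            raise ValueError("bp_end must be >= bp_start")


@dataclass(frozen=True)
class PerturbationSpec:
    """Injectable structural events plus thermal jitter."""

    bubbles: tuple[BubbleSpec, ...] = ()
    motif_regions: tuple[MotifSpec, ...] = ()
    noise_sd: float = 0.15  # Å per atom coordinate
    salt_label: float = 200.0  # mM, metadata
    #: optional hook scaling bubble severity by salt label (e.g. {50: 1.0,
    #: 200: 0.8} to emulate duplex stabilisation at high salt); no
    #: electrostatics are computed
    salt_severity_factors: dict | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def effective_severity(self, spec: "BubbleSpec") -> float:
        if not self.salt_severity_factors:
            return spec.severity
        factor = self.salt_severity_factors.get(self.salt_label, 1.0)
        return min(1.0, spec.severity * factor)

    def validate(self, n_bp: int, n_steps: int) -> None:
        regions = [(b.bp_start, b.bp_end, "bubble") for b in self.bubbles]
        regions += [(m.bp_start, m.bp_end, m.mode) for m in self.motif_regions]
        for lo, hi, kind in regions:
            if not (1 <= lo <= hi <= n_bp):
                raise ValueError(f"{kind} range {lo}-{hi} outside 1..{n_bp}")
        for spec in (*self.bubbles, *self.motif_regions):
            if not 1 <= spec.onset_window <= n_steps:
                raise ValueError(
                    f"onset window {spec.onset_window} outside 1..{n_steps}"
                )
        overlaps = []
        for b in self.bubbles:
            for m in self.motif_regions:
                if b.bp_start <= m.bp_end and m.bp_start <= b.bp_end:
                    overlaps.append(((b.bp_start, b.bp_end), (m.bp_start, m.bp_end)))
        if overlaps:
            raise ValueError(f"bubble and motif regions overlap: {overlaps}")


@dataclass
class Trajectory:
    """Ordered frames grouped into stretch windows."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    window_index: np.ndarray  # (n_frames,), 1-based
    extension_A: np.ndarray  # (n_windows,)
    percent_extension: np.ndarray  # (n_windows,)
    protocol: StretchProtocol
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    @property
    def n_windows(self) -> int:
        return len(self.extension_A)

    def window_frames(self, window: int) -> np.ndarray:
        return self.coords[self.window_index == window]


# rotation scale for a fully disrupted pair: each base swings 60° in-plane,
# moving its WC edge ~5 Å off its partner's
_BUBBLE_MAX_ANGLE = 60.0
# in-plane cross-helix shifts (Å) toward strand 2; both leave the base in its
# own pair plane so no steric blow-up occurs with the neighbouring planes.
# 1.5 Å strengthens the inter-strand diagonal vdW contacts while keeping the
# WC bonds intact; 2.8 Å pushes the base past its partner into a shifted
# register where its donors/acceptors meet the partner's non-WC atoms,
# replacing canonical H-bonds with non-canonical ones.
_MOTIF_SHIFT_STACK = 1.5
_MOTIF_SHIFT_HBOND = 2.8


def _rotation(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(degrees)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0.0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


class _Deformer:
    """Precomputed index machinery for applying perturbations to one duplex."""

    def __init__(self, duplex: Duplex):
        self.table = duplex.atom_table()
        self.duplex = duplex
        n = duplex.n_bp
        roles = self.table["role"].to_numpy()
        self.base_mask = np.char.startswith(roles.astype(str), "base")
        bp = self.table["bp"].to_numpy()
        strand = self.table["strand"].to_numpy()
        names = self.table["name"].to_numpy()
        coords0 = duplex.coordinates()

        self.base_idx = {}  # (bp, strand) -> base-atom indices
        self.c1_pos = {}  # (bp, strand) -> C1' position in the reference frame
        for b in range(1, n + 1):
            for s in (1, 2):
                sel = (bp == b) & (strand == s)
                self.base_idx[(b, s)] = np.flatnonzero(sel & self.base_mask)
                c1 = np.flatnonzero(sel & (names == "C1'"))
                self.c1_pos[(b, s)] = coords0[c1[0]]
        self.terminal_mask = self.table["terminal"].to_numpy()
        self.frac = (bp - 1) / (n - 1) if n > 1 else np.zeros(len(bp))

    def pair_axis(self, b: int) -> np.ndarray:
        """In-plane unit vector from strand-2 C1' to strand-1 C1' of bp b."""
        v = self.c1_pos[(b, 1)] - self.c1_pos[(b, 2)]
        v[2] = 0.0
        return v / np.linalg.norm(v)

    def apply_bubble(self, coords: np.ndarray, spec: BubbleSpec,
                     severity: float | None = None) -> None:
        """Swing both bases of each pair in-plane, away from WC geometry."""
        ang = (severity if severity is not None else spec.severity) \
            * _BUBBLE_MAX_ANGLE
        for b in range(spec.bp_start, spec.bp_end + 1):
            for s, sign in ((1, +1.0), (2, -1.0)):
                idx = self.base_idx[(b, s)]
                # vertical rotation axis through this nucleotide's C1'
                pivot = self.c1_pos[(b, s)]
                R = _rotation(np.array([0.0, 0.0, 1.0]), sign * ang)
                coords[idx] = (coords[idx] - pivot) @ R.T + pivot

    def apply_motif(self, coords: np.ndarray, spec: MotifSpec) -> None:
        """Shift strand-1 bases across the helix toward strand 2 in-plane."""
        delta = (_MOTIF_SHIFT_HBOND if spec.mode == "non-canonical-hbond"
                 else _MOTIF_SHIFT_STACK)
        for b in range(spec.bp_start, spec.bp_end + 1):
            idx = self.base_idx[(b, 1)]
            coords[idx] = coords[idx] - delta * self.pair_axis(b)


def generate_trajectory(duplex: Duplex, protocol: StretchProtocol | None = None,
                        perturbation: PerturbationSpec | None = None,
                        seed: int = 0) -> Trajectory:
    """Generate a seeded synthetic stretching trajectory for a duplex."""
    protocol = protocol or StretchProtocol()
    perturbation = perturbation or PerturbationSpec()
    n = duplex.n_bp
    perturbation.validate(n, protocol.n_steps)
    rng = np.random.default_rng(seed)
    deform = _Deformer(duplex)
    coords0 = duplex.coordinates()
    n_atoms = len(coords0)

    contour = (n - 1) * duplex.helical_params.rise0
    extensions = protocol.step_size * np.arange(1, protocol.n_steps + 1)
    percent = 100.0 * extensions / contour if contour > 0 else np.zeros_like(extensions)

    frames = np.empty((protocol.n_steps * protocol.frames_per_window, n_atoms, 3))
    window_index = np.empty(len(frames), dtype=int)
    interior = ~deform.terminal_mask
    k = 0
    for w in range(1, protocol.n_steps + 1):
        base = coords0.copy()
        base[:, 2] += extensions[w - 1] * deform.frac
        for spec in perturbation.bubbles:
            if w >= spec.onset_window:
                deform.apply_bubble(base, spec,
                                    perturbation.effective_severity(spec))
        for spec in perturbation.motif_regions:
            if w >= spec.onset_window:
                deform.apply_motif(base, spec)
        for _ in range(protocol.frames_per_window):
            frame = base.copy()
            if perturbation.noise_sd > 0:
                jitter = rng.normal(0.0, perturbation.noise_sd, size=(n_atoms, 3))
                frame[interior] += jitter[interior]
            frames[k] = frame
            window_index[k] = w
            k += 1
    return Trajectory(
        coords=frames, window_index=window_index, extension_A=extensions,
        percent_extension=percent, protocol=protocol,
        metadata={
            "sequence": duplex.sequence,
            "sigma": duplex.supercoil.sigma if duplex.supercoil else 0.0,
            "salt_label": perturbation.salt_label,
            "seed": seed,
            "window_time_ps": protocol.window_time,
            "trap_constant": protocol.trap_constant,
        },
    )


@dataclass(frozen=True)
class RunDescriptor:
    sequence_name: str
    sequence: str
    sigma: float
    salt_label: float
    seed: int


def derive_seed(master_seed: int, sequence: str, sigma: float, salt: float) -> int:
    """Deterministic per-run seed: CRC32 of the factor labels XOR master."""
    tag = f"{sequence}|{sigma:+.4f}|{salt:g}".encode()
    return (zlib.crc32(tag) ^ (master_seed & 0x7FFFFFFF)) & 0x7FFFFFFF


def design_matrix(sequences: dict[str, str] | None = None,
                  sigmas: tuple[float, ...] = SIGMA_GRID,
                  salts: tuple[float, ...] = SALT_LABELS,
                  master_seed: int = 0,
                  protocol: StretchProtocol | None = None):
    """Enumerate the full study: sequences x sigma grid x salt labels.

    Returns ``(runs, total_time_ps)`` where the total simulated-time metadata
    is runs x windows x window duration.
    """
    sequences = sequences if sequences is not None else STUDY_SEQUENCES
    protocol = protocol or StretchProtocol()
    if not sequences or not sigmas or not salts:
        raise ValueError("design matrix factors must all be non-empty")
    runs = [
        RunDescriptor(name, seq, sigma, salt,
                      derive_seed(master_seed, seq, sigma, salt))
        for (name, seq), sigma, salt
        in itertools.product(sequences.items(), sigmas, salts)
    ]
    total_time_ps = len(runs) * protocol.n_steps * protocol.window_time
    return runs, total_time_ps


def generate_force_table(duplex: Duplex, protocol: StretchProtocol | None = None,
                         spring_k: float = 2.0, noise_sd_force: float = 5.0,
                         seed: int = 0,
                         extension_A: float | None = None,
                         n_frames: int | None = None) -> ForceFrames:
    """Synthetic per-atom force records for the force-estimator fixture.

    Terminal backbone atoms carry an axial (z) force ``spring_k * extension``
    in pN plus zero-mean Gaussian noise; every other atom carries noise only.
    By default frames follow the stretching schedule (extension grows with
    the window); passing ``extension_A`` holds the extension fixed instead,
    with ``n_frames`` frames.
    """
    protocol = protocol or StretchProtocol()
    if spring_k < 0:
        raise ValueError("spring_k must be >= 0")
    rng = np.random.default_rng(seed)
    atoms = duplex.atom_table()
    terminal_backbone = (atoms["terminal"] & (atoms["role"] == "backbone")).to_numpy()
    if extension_A is not None:
        n_frames = n_frames or protocol.frames_per_window
        ext_per_frame = np.full(n_frames, float(extension_A))
        window = np.ones(n_frames, dtype=int)
    else:
        extensions = protocol.step_size * np.arange(1, protocol.n_steps + 1)
        ext_per_frame = np.repeat(extensions, protocol.frames_per_window)
        window = np.repeat(np.arange(1, protocol.n_steps + 1),
                           protocol.frames_per_window)
    n_at = len(atoms)
    forces = (rng.normal(0.0, noise_sd_force, size=(len(ext_per_frame), n_at, 3))
              if noise_sd_force > 0 else np.zeros((len(ext_per_frame), n_at, 3)))
    forces[:, terminal_backbone, 2] += spring_k * ext_per_frame[:, None]
    return ForceFrames(forces=forces, atoms=atoms, window_index=window)
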