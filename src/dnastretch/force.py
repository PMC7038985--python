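"""Control-corrected mean end-to-end force estimation.

The estimator mirrors the tweezers-style bookkeeping used for restrained
stretching simulations: a named set of backbone atoms on the terminal base
pairs is selected, the axial (z) force component is averaged over that set
per frame, and the mean over the pulling run is corrected by subtracting the
mean of a restraint-free control run under otherwise identical conditions.
The standard error combines the two runs' per-frame distributions, treating
frames as uncorrelated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default named backbone set per terminal residue ("nine backbone atoms")
DEFAULT_BACKBONE_ATOMS = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'", "O4'")


@dataclass
class ForceFrames:
    """Per-frame per-atom force vectors (pN) with atom metadata.

    ``atoms`` carries at least serial, name, role, residue_index, strand and
    a ``terminal`` flag marking the terminal base pairs.
    """

    forces: np.ndarray  # (n_frames, n_atoms, 3)
    atoms: pd.DataFrame
    window_index: np.ndarray | None = None

    def __post_init__(self):
        if self.forces.ndim != 3 or self.forces.shape[2] != 3:
            raise ValueError("forces must have shape (n_frames, n_atoms, 3)")
        if len(self.forces) < 1:
            raise ValueError("need at least one frame")
        if not np.all(np.isfinite(self.forces)):
            raise ValueError("force components must be finite")
        if self.forces.shape[1] != len(self.atoms):
            raise ValueError("force array and atom table lengths differ")


@dataclass(frozen=True)
class ForceEstimate:
    """Corrected mean end-to-end force, pN."""

    f_avg: float
    sem: float
    n_frames: int
    corrected: bool

    def __post_init__(self):
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


def _select_terminal_backbone(frames: ForceFrames,
                              backbone_selection: tuple[str, ...]) -> np.ndarray:
    atoms = frames.atoms
    terminal = atoms["terminal"].to_numpy().astype(bool)
    in_set = atoms["name"].isin(backbone_selection).to_numpy()
    sel = terminal & in_set
    if not sel.any():
        available = sorted(set(atoms.loc[terminal, "name"]))
        raise ValueError(
            "backbone selection matched no terminal atoms; terminal residues "
            f"carry: {available}"
        )
    # 5'-terminal residues may lack phosphate atoms in other inputs
    missing = set(backbone_selection) - set(atoms.loc[sel, "name"])
    if missing:
        logger.warning("terminal residues lack %s; using the available subset",
                       sorted(missing))
    return sel


def per_frame_axial_force(frames: ForceFrames,
                          backbone_selection: tuple[str, ...] = DEFAULT_BACKBONE_ATOMS,
                          ) -> np.ndarray:
    """Mean axial (z) force over the selected terminal backbone atoms, per frame."""
    sel = _select_terminal_backbone(frames, backbone_selection)
    return frames.forces[:, sel, 2].mean(axis=1)


def estimate_force(pull: ForceFrames, control: ForceFrames | None = None,
                   backbone_selection: tuple[str, ...] = DEFAULT_BACKBONE_ATOMS,
                   ) -> ForceEstimate:
    """Control-corrected mean end-to-end force with its standard error.

    ``f_avg`` is the mean per-frame axial force of the pulling run minus the
    control run's; the SEM pools the two runs' per-frame variances
    (sqrt(s²_pull/n_pull + s²_ctrl/n_ctrl)), frames treated as uncorrelated.
    Without a control the estimate is reported uncorrected.
    """
    fp = per_frame_axial_force(pull, backbone_selection)
    if control is not None:
        fc = per_frame_axial_force(control, backbone_selection)
        f_avg = float(fp.mean() - fc.mean())
        var_p = float(fp.var(ddof=1)) if len(fp) > 1 else 0.0
        var_c = float(fc.var(ddof=1)) if len(fc) > 1 else 0.0
        sem = float(np.sqrt(var_p / len(fp) + var_c / len(fc)))
        return ForceEstimate(f_avg, sem, len(fp) + len(fc), True)
    f_avg = float(fp.mean())
    sem = float(fp.std(ddof=1) / np.sqrt(len(fp))) if len(fp) > 1 else 0.0
    return ForceEstimate(f_avg, sem, len(fp), False)


# -- TSV interchange ----------------------------------------------------------

def write_force_table(path, frames: ForceFrames) -> None:
    """Write the per-frame per-atom force table as TSV (forces in pN)."""
    n_frames, n_atoms, _ = frames.forces.shape
    df = pd.DataFrame({
        "frame": np.repeat(np.arange(1, n_frames + 1), n_atoms),
        "atom_serial": np.tile(frames.atoms["serial"].to_numpy(), n_frames),
        "fx": frames.forces[:, :, 0].ravel(),
        "fy": frames.forces[:, :, 1].ravel(),
        "fz": frames.forces[:, :, 2].ravel(),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_force_table(path, atoms: pd.DataFrame) -> ForceFrames:
    """Read a TSV force table; ``atoms`` supplies the metadata by serial."""
    df = pd.read_csv(path, sep="\t")
    frames_ids = np.sort(df["frame"].unique())
    n_atoms = len(atoms)
    forces = np.empty((len(frames_ids), n_atoms, 3))
    order = atoms["serial"].to_numpy()
    for k, fr in enumerate(frames_ids):
        sub = df[df["frame"] == fr].set_index("atom_serial")
        if len(sub) != n_atoms:
            raise ValueError(f"frame {fr} has {len(sub)} atoms, expected {n_atoms}")
        sub = sub.loc[order]
        forces[k] = sub[["fx", "fy", "fz"]].to_numpy()
    return ForceFrames(forces=forces, atoms=atoms)
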