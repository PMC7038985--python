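"""PDB, TSV and JSON interchange.

PDB dialect: residue names DA/DT/DG/DC; chain A is strand 1, chain B strand
2; contiguous serial numbering; occupancy 1.00; sugar atoms use prime names
(C1', O5', ...).  Trajectories are multi-model files (MODEL/ENDMDL per
frame) with an optional JSON sidecar carrying window structure and run
metadata; without the sidecar each model is read back as its own window.

Metric matrices are written as four TSV files (rows = bp labels, columns =
percent extension with one decimal) plus a JSON sidecar with the labels,
protocol and run conditions.  Bubble lists are TSV (window, start, end,
size).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .duplex import Duplex
from .metrics import CHANNELS, MeltingBubble, MetricsMatrix
from .trajectory import StretchProtocol, Trajectory

_RES_NAMES = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}


def _atom_array(duplex: Duplex, coords: np.ndarray) -> struc.AtomArray:
    table = duplex.atom_table()
    n = len(table)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.where(table["strand"].to_numpy() == 1, "A", "B")
    arr.res_id = table["residue_index"].to_numpy()
    arr.res_name = np.array([_RES_NAMES[b] for b in table["base"]])
    arr.atom_name = table["name"].to_numpy().astype(str)
    arr.element = table["element"].to_numpy().astype(str)
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("b_factor", np.zeros(n))
    return arr


def write_duplex_pdb(path, duplex: Duplex) -> None:
    """Write a duplex as a single-model PDB file."""
    f = pdb.PDBFile()
    f.set_structure(_atom_array(duplex, duplex.coordinates()))
    f.write(str(path))


def write_trajectory(path, duplex: Duplex, trajectory: Trajectory,
                     sidecar: bool = True) -> None:
    """Write a trajectory as multi-model PDB (+ JSON window sidecar)."""
    template = _atom_array(duplex, trajectory.coords[0])
    stack = struc.from_template(template, trajectory.coords.astype(np.float32))
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))
    if sidecar:
        meta = {
            "window_index": trajectory.window_index.tolist(),
            "extension_A": trajectory.extension_A.tolist(),
            "percent_extension": trajectory.percent_extension.tolist(),
            "protocol": {
                "step_size": trajectory.protocol.step_size,
                "n_steps": trajectory.protocol.n_steps,
                "frames_per_window": trajectory.protocol.frames_per_window,
                "window_time": trajectory.protocol.window_time,
                "trap_constant": trajectory.protocol.trap_constant,
            },
            "metadata": trajectory.metadata,
        }
        Path(str(path) + ".json").write_text(
            json.dumps(meta, indent=1, sort_keys=True) + "\n"
        )


def _check_model_consistency(path) -> None:
    """Reject multi-model files whose models differ in atom count."""
    counts: dict[int, int] = {}
    model = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                model = int(line.split()[1])
                counts[model] = 0
            elif line.startswith(("ATOM", "HETATM")):
                counts[model if model is not None else 1] = \
                    counts.get(model if model is not None else 1, 0) + 1
    if len(set(counts.values())) > 1:
        ref = max(set(counts.values()), key=lambda v: sum(c == v for c in counts.values()))
        bad = sorted(m for m, c in counts.items() if c != ref)
        raise ValueError(
            f"inconsistent atom count across models: MODEL records {bad} "
            f"differ from the majority count {ref}"
        )


def read_trajectory(path) -> Trajectory:
    """Read a multi-model PDB trajectory (frames in model order).

    Window structure and metadata are restored from the ``<path>.json``
    sidecar when present; otherwise every model becomes its own
    unit-extension window.
    """
    _check_model_consistency(path)
    f = pdb.PDBFile.read(str(path))
    stack = f.get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float)
    n_frames = len(coords)
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        protocol = StretchProtocol(**meta["protocol"])
        return Trajectory(
            coords=coords,
            window_index=np.asarray(meta["window_index"], dtype=int),
            extension_A=np.asarray(meta["extension_A"], dtype=float),
            percent_extension=np.asarray(meta["percent_extension"], dtype=float),
            protocol=protocol,
            metadata=meta.get("metadata", {}),
        )
    protocol = StretchProtocol(n_steps=n_frames, frames_per_window=1)
    ext = np.arange(1, n_frames + 1, dtype=float)
    return Trajectory(
        coords=coords,
        window_index=np.arange(1, n_frames + 1),
        extension_A=ext,
        percent_extension=ext,
        protocol=protocol,
        metadata={},
    )


# -- metrics / bubbles / motifs -----------------------------------------------

def write_metrics(outdir, matrix: MetricsMatrix, prefix: str = "metrics") -> list[Path]:
    """Write the four channel TSVs plus the JSON sidecar; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [f"{x:.1f}" for x in matrix.window_labels]
    paths = []
    for name in CHANNELS:
        df = pd.DataFrame(matrix.channel(name), index=matrix.bp_labels, columns=cols)
        df.index.name = "bp"
        p = outdir / f"{prefix}_{name}.tsv"
        df.to_csv(p, sep="\t", float_format="%.6f")
        paths.append(p)
    sidecar = outdir / f"{prefix}.json"
    sidecar.write_text(json.dumps({
        "bp_labels": matrix.bp_labels.tolist(),
        "percent_extension": matrix.window_labels.tolist(),
        "channels": list(CHANNELS),
        "metadata": matrix.metadata,
    }, indent=1, sort_keys=True) + "\n")
    paths.append(sidecar)
    return paths


def read_metrics(outdir, prefix: str = "metrics") -> MetricsMatrix:
    outdir = Path(outdir)
    meta = json.loads((outdir / f"{prefix}.json").read_text())
    channels = {}
    for name in CHANNELS:
        df = pd.read_csv(outdir / f"{prefix}_{name}.tsv", sep="\t", index_col="bp")
        channels[name] = df.to_numpy()
    return MetricsMatrix(
        bp_labels=np.asarray(meta["bp_labels"], dtype=int),
        window_labels=np.asarray(meta["percent_extension"], dtype=float),
        channels=channels,
        metadata=meta.get("metadata", {}),
    )


def write_bubbles(path, bubbles: list[MeltingBubble]) -> None:
    df = pd.DataFrame(
        [(b.window, b.bp_start, b.bp_end, b.size) for b in bubbles],
        columns=["window", "bp_start", "bp_end", "size"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_motifs(path, labels: np.ndarray, matrix: MetricsMatrix) -> None:
    cols = [f"{x:.1f}" for x in matrix.window_labels]
    df = pd.DataFrame(labels, index=matrix.bp_labels, columns=cols)
    df.index.name = "bp"
    df.to_csv(path, sep="\t")
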