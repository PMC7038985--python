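"""End-to-end orchestration: build -> supercoil -> simulate -> analyse -> write.

Every output file is a deterministic function of (config, seed): stage
wall-times are logged to the console only, while the written run log carries
the config hash, seed, library versions and record counts.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .duplex import HelicalParams, build_duplex, impose_supercoiling
from .force import estimate_force, write_force_table
from .metrics import (
    analyze_trajectory,
    bubbles_in_matrix,
    classify_motifs,
    scheme_for_sequence,
    trim_ends,
)
from .pdbio import write_bubbles, write_duplex_pdb, write_metrics, write_motifs, \
    write_trajectory
from .trajectory import generate_force_table, generate_trajectory

logger = logging.getLogger(__name__)


def _stage(log_records, name, fn):
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception:
        logger.error("stage %s failed", name)
        log_records.append({"stage": name, "status": "failed"})
        raise
    dt = time.perf_counter() - t0
    logger.info("stage %s done in %.2f s", name, dt)
    log_records.append({"stage": name, "status": "ok"})
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Run one configured stretching study; returns a manifest of outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    params = HelicalParams(config.twist0, config.rise0, len(config.bases))
    duplex = _stage(stages, "build", lambda: build_duplex(config.bases, params))
    if config.sigma != 0.0:
        duplex = _stage(stages, "deform",
                        lambda: impose_supercoiling(duplex, config.sigma))
    protocol = config.protocol.build()
    perturbation = config.perturbation.build(config.salt_label)
    trajectory = _stage(stages, "simulate", lambda: generate_trajectory(
        duplex, protocol, perturbation, seed=config.seed))

    write_duplex_pdb(outdir / "duplex.pdb", duplex)
    _stage(stages, "write-trajectory",
           lambda: write_trajectory(outdir / "trajectory.pdb", duplex, trajectory))

    matrix = _stage(stages, "analyze",
                    lambda: analyze_trajectory(duplex, trajectory))
    trimmed = trim_ends(matrix, config.n_trim) if config.n_trim else matrix
    _stage(stages, "write-metrics", lambda: write_metrics(outdir, trimmed))

    bubbles = _stage(stages, "bubbles", lambda: bubbles_in_matrix(trimmed))
    write_bubbles(outdir / "bubbles.tsv", bubbles)

    scheme = config.scheme or (
        scheme_for_sequence(config.sequence).name
        if config.sequence in ("(AA)12", "(AT)12", "(CC)12", "(CG)12") else None
    )
    if scheme is not None:
        labels = _stage(stages, "motifs", lambda: classify_motifs(trimmed, scheme))
        write_motifs(outdir / "motifs.tsv", labels, trimmed)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"dnastretch": __version__, "numpy": np.__version__},
        "records": {
            "n_frames": trajectory.n_frames,
            "n_windows": trajectory.n_windows,
            "n_bp_retained": int(len(trimmed.bp_labels)),
            "n_bubbles": len(bubbles),
        },
        "stages": stages,
        "scheme": scheme,
    }

    if config.force.enabled:
        pull = generate_force_table(
            duplex, protocol, spring_k=config.force.spring_k,
            noise_sd_force=config.force.noise_sd, seed=config.seed + 1)
        control = generate_force_table(
            duplex, protocol, spring_k=0.0,
            noise_sd_force=config.force.noise_sd, seed=config.seed + 2)
        write_force_table(outdir / "force_table.tsv", pull)
        est = _stage(stages, "force", lambda: estimate_force(pull, control))
        (outdir / "force.json").write_text(json.dumps({
            "f_avg_pN": est.f_avg, "sem_pN": est.sem,
            "n_frames": est.n_frames, "corrected": est.corrected,
        }, indent=1, sort_keys=True) + "\n")
        manifest["records"]["force_frames"] = est.n_frames

    (outdir / "run_log.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def run_study(runs, protocol=None, noise_sd: float = 0.15, n_trim: int = 2):
    """Analyse every run of a design matrix in memory.

    For each run descriptor the duplex is built, supercoiled, stretched and
    analysed; returns a list of per-run summaries (channel means over the
    trimmed matrix, bubble statistics) without writing files.
    """
    from .metrics import bubble_timeseries, trim_ends
    from .metrics import analyze_trajectory as _analyze
    from .trajectory import PerturbationSpec, StretchProtocol, \
        generate_trajectory

    protocol = protocol or StretchProtocol(frames_per_window=10)
    summaries = []
    for run in runs:
        duplex = build_duplex(run.sequence)
        if run.sigma != 0.0:
            duplex = impose_supercoiling(duplex, run.sigma)
        perturbation = PerturbationSpec(noise_sd=noise_sd,
                                        salt_label=run.salt_label)
        traj = generate_trajectory(duplex, protocol, perturbation,
                                   seed=run.seed)
        matrix = trim_ends(_analyze(duplex, traj), n_trim)
        series = bubble_timeseries(matrix)
        summaries.append({
            "sequence": run.sequence_name,
            "sigma": run.sigma,
            "salt": run.salt_label,
            "seed": run.seed,
            "mean_canonical_hb": float(matrix.channel("canonical_hb").mean()),
            "mean_noncanonical_hb": float(
                matrix.channel("noncanonical_hb").mean()),
            "mean_canonical_stack": float(
                matrix.channel("canonical_stack").mean()),
            "mean_noncanonical_stack": float(
                matrix.channel("noncanonical_stack").mean()),
            "max_bubble_bp": int(series.max()),
            "n_windows": int(traj.n_windows),
            "n_frames": int(traj.n_frames),
        })
    return summaries
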