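"""Per-window per-bp aggregation, melting bubbles, and motif classification.

Frames are averaged per stretch window into a four-channel matrix (canonical
and non-canonical H-bond counts per bp; canonical and non-canonical stacking
energies in kcal/mol per bp).  Two base pairs at each end of the fragment are
trimmed before any downstream analysis to avoid end effects, so a 24-bp
fragment is reported over bp 3..22.

A melting bubble is a maximal run of two or more sequential base pairs whose
window-averaged canonical Watson-Crick H-bond count is strictly below one.
The bubble time series counts bp involved in any bubble per window.

Motif classification maps each (bp, window) cell to a colour label via named
per-sequence rule schemes modelled on the published colouring criteria;
"loss" and "gain" channels are computed against a designated baseline window
(the first by default).  Rules are evaluated in precedence order; unmatched
cells are labelled ``background``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .duplex import Duplex
from .interactions import FrameAnalyzer, HBondCriteria, LJTable
from .trajectory import Trajectory

CHANNELS = ("canonical_hb", "noncanonical_hb", "canonical_stack", "noncanonical_stack")


@dataclass
class MetricsMatrix:
    """bp-by-window averages of the four interaction channels."""

    bp_labels: np.ndarray  # (n_bp,) 1-based bp indices retained
    window_labels: np.ndarray  # (n_windows,) percent extension
    channels: dict  # name -> (n_bp, n_windows) array
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        want = (len(self.bp_labels), len(self.window_labels))
        for name, shape in shapes.items():
            if shape != want:
                raise ValueError(f"channel {name} has shape {shape}, expected {want}")
        if np.any(np.diff(self.window_labels) <= 0):
            raise ValueError("window labels must be strictly increasing")

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"missing channel {name!r}; have {sorted(self.channels)}")
        return self.channels[name]


@dataclass(frozen=True)
class MeltingBubble:
    """Maximal run of consecutive bp below the WC-bond threshold."""

    window: int
    bp_start: int
    bp_end: int

    @property
    def size(self) -> int:
        return self.bp_end - self.bp_start + 1


def analyze_trajectory(duplex: Duplex, trajectory: Trajectory,
                       criteria: HBondCriteria | None = None,
                       lj: LJTable | None = None) -> MetricsMatrix:
    """Run per-frame interaction analysis and aggregate it per window."""
    analyzer = FrameAnalyzer(duplex, criteria=criteria, lj=lj)
    per_frame = [analyzer.per_bp_channels(frame) for frame in trajectory.coords]
    return aggregate_windows(trajectory, per_frame)


def aggregate_windows(trajectory: Trajectory, per_frame_channels: list[dict],
                      ) -> MetricsMatrix:
    """Arithmetic mean of per-frame per-bp channels within each window."""
    if len(per_frame_channels) != trajectory.n_frames:
        raise ValueError("one channel record per frame is required")
    n_windows = trajectory.n_windows
    n_bp = len(per_frame_channels[0][CHANNELS[0]])
    out = {name: np.zeros((n_bp, n_windows)) for name in CHANNELS}
    for w in range(1, n_windows + 1):
        members = np.flatnonzero(trajectory.window_index == w)
        if len(members) == 0:
            raise ValueError(f"window {w} has no frames")
        for name in CHANNELS:
            out[name][:, w - 1] = np.mean(
                [per_frame_channels[k][name] for k in members], axis=0
            )
    return MetricsMatrix(
        bp_labels=np.arange(1, n_bp + 1),
        window_labels=trajectory.percent_extension.copy(),
        channels=out,
        metadata=dict(trajectory.metadata),
    )


def trim_ends(matrix: MetricsMatrix, n_trim: int = 2) -> MetricsMatrix:
    """Drop ``n_trim`` bp from each end (end-effect exclusion)."""
    n_bp = len(matrix.bp_labels)
    if n_bp < 2 * n_trim + 1:
        raise ValueError(
            f"cannot trim {n_trim} bp per end from a {n_bp}-bp matrix"
        )
    sl = slice(n_trim, n_bp - n_trim)
    return MetricsMatrix(
        bp_labels=matrix.bp_labels[sl].copy(),
        window_labels=matrix.window_labels.copy(),
        channels={k: v[sl].copy() for k, v in matrix.channels.items()},
        metadata=dict(matrix.metadata),
    )


def detect_bubbles(canonical_hb_row: np.ndarray, window: int = 1,
                   bp_labels: np.ndarray | None = None,
                   threshold: float = 1.0) -> list[MeltingBubble]:
    """Maximal runs (length >= 2) of bp with mean canonical H-bonds < threshold.

    The threshold is strict: values exactly at ``threshold`` do not melt.
    """
    row = np.asarray(canonical_hb_row, dtype=float)
    if np.any(row < 0):
        raise ValueError("canonical H-bond means must be >= 0")
    labels = (np.asarray(bp_labels) if bp_labels is not None
              else np.arange(1, len(row) + 1))
    below = row < threshold
    out: list[MeltingBubble] = []
    i = 0
    while i < len(row):
        if below[i]:
            j = i
            while j + 1 < len(row) and below[j + 1]:
                j += 1
            if j - i + 1 >= 2:
                out.append(MeltingBubble(window, int(labels[i]), int(labels[j])))
            i = j + 1
        else:
            i += 1
    return out


def bubbles_in_matrix(matrix: MetricsMatrix) -> list[MeltingBubble]:
    """All melting bubbles across the matrix, window by window."""
    rows = matrix.channel("canonical_hb")
    out: list[MeltingBubble] = []
    for w in range(rows.shape[1]):
        out.extend(detect_bubbles(rows[:, w], window=w + 1,
                                  bp_labels=matrix.bp_labels))
    return out


def bubble_timeseries(matrix: MetricsMatrix) -> np.ndarray:
    """Number of bp involved in a melting bubble, per window."""
    counts = np.zeros(len(matrix.window_labels), dtype=int)
    for b in bubbles_in_matrix(matrix):
        counts[b.window - 1] += b.size
    return counts


# -- motif classification -----------------------------------------------------

#: cell quantities a rule condition may reference; loss/gain/change are taken
#: against the designated baseline window
_QUANTITIES = (
    "canonical_hb", "noncanonical_hb", "canonical_stack", "noncanonical_stack",
    "canonical_hb_loss", "noncanonical_hb_gain",
    "canonical_stack_change", "noncanonical_stack_change",
    "noncanonical_stack_change_abs",
)


@dataclass(frozen=True)
class Condition:
    """One threshold test: ``quantity op value`` (or |quantity-value|<=tol)."""

    quantity: str
    op: str  # ">", "<", ">=", "<=", "approx"
    value: float
    tol: float = 0.0

    def __post_init__(self):
        if self.quantity not in _QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.op not in (">", "<", ">=", "<=", "approx"):
            raise ValueError(f"unknown operator {self.op!r}")

    def evaluate(self, cell: dict) -> bool:
        x = cell[self.quantity]
        if self.op == ">":
            return x > self.value
        if self.op == "<":
            return x < self.value
        if self.op == ">=":
            return x >= self.value
        if self.op == "<=":
            return x <= self.value
        return abs(x - self.value) <= self.tol


@dataclass(frozen=True)
class MotifRule:
    label: str
    conditions: tuple[Condition, ...]

    def matches(self, cell: dict) -> bool:
        return all(c.evaluate(cell) for c in self.conditions)


@dataclass(frozen=True)
class MotifScheme:
    """Ordered rules; the first match wins, no match -> ``background``."""

    name: str
    rules: tuple[MotifRule, ...]


def _rule(label, *conds):
    return MotifRule(label, tuple(Condition(*c) for c in conds))


#: published per-sequence colouring criteria (implicit-solvent heatmaps);
#: the CG-yellow tolerance bands (±0.5 bond, ±5 kcal/mol) are configurable
#: by building a modified scheme.
SCHEMES = {
    "AA": MotifScheme("AA", (
        _rule("red", ("noncanonical_hb", ">", 2.0)),
        _rule("blue", ("noncanonical_hb", "<", 2.0),
              ("noncanonical_stack", "<", 0.0)),
    )),
    "AT": MotifScheme("AT", (
        _rule("red", ("noncanonical_hb", ">", 2.0)),
        _rule("blue", ("noncanonical_hb", "<", 2.0)),
    )),
    "CC": MotifScheme("CC", (
        _rule("green", ("canonical_hb_loss", ">=", 1.0)),
    )),
    "CG": MotifScheme("CG", (
        _rule("yellow",
              ("canonical_hb_loss", "approx", 2.0, 0.5),
              ("noncanonical_hb_gain", "approx", 1.0, 0.5),
              ("noncanonical_stack_change_abs", "approx", 20.0, 5.0)),
    )),
    # alternative thresholds used for the explicit-solvent figure captions
    "AT-explicit": MotifScheme("AT-explicit", (
        _rule("red", ("noncanonical_hb", ">", 1.0)),
        _rule("blue", ("noncanonical_stack", "<", -10.0)),
    )),
    "CC-explicit": MotifScheme("CC-explicit", (
        _rule("red", ("canonical_hb_loss", ">", 1.0)),
    )),
}


def classify_motifs(matrix: MetricsMatrix, scheme: MotifScheme | str,
                    baseline_window: int = 1) -> np.ndarray:
    """Label every (bp, window) cell by the scheme's precedence order.

    Returns an object array of labels with the matrix's shape; cells
    matching no rule are ``"background"``.
    """
    if isinstance(scheme, str):
        if scheme not in SCHEMES:
            raise KeyError(f"unknown scheme {scheme!r}; have {sorted(SCHEMES)}")
        scheme = SCHEMES[scheme]
    for rule in scheme.rules:
        for cond in rule.conditions:
            if cond.quantity.split("_loss")[0].split("_gain")[0] \
                   .split("_change")[0] not in CHANNELS:
                raise KeyError(f"scheme references missing channel {cond.quantity!r}")
    n_bp, n_win = len(matrix.bp_labels), len(matrix.window_labels)
    if not 1 <= baseline_window <= n_win:
        raise ValueError(f"baseline window {baseline_window} outside 1..{n_win}")
    b = baseline_window - 1
    base = {name: matrix.channel(name)[:, b] for name in CHANNELS}
    labels = np.full((n_bp, n_win), "background", dtype=object)
    for i in range(n_bp):
        for w in range(n_win):
            cell = {name: matrix.channel(name)[i, w] for name in CHANNELS}
            cell["canonical_hb_loss"] = base["canonical_hb"][i] - cell["canonical_hb"]
            cell["noncanonical_hb_gain"] = (cell["noncanonical_hb"]
                                            - base["noncanonical_hb"][i])
            cell["canonical_stack_change"] = (cell["canonical_stack"]
                                              - base["canonical_stack"][i])
            cell["noncanonical_stack_change"] = (cell["noncanonical_stack"]
                                                 - base["noncanonical_stack"][i])
            cell["noncanonical_stack_change_abs"] = abs(
                cell["noncanonical_stack_change"])
            for rule in scheme.rules:
                if rule.matches(cell):
                    labels[i, w] = rule.label
                    break
    return labels


def scheme_for_sequence(sequence_name: str) -> MotifScheme:
    """Default scheme for one of the study sequences ('(AA)12' -> 'AA')."""
    key = sequence_name.strip("()0123456789")
    if key in SCHEMES:
        return SCHEMES[key]
    raise KeyError(f"no default scheme for sequence {sequence_name!r}")
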