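"""Oscillating transcription-factor subnetwork and cell-cycle phase calling.

A generic TF->target edge list (YEASTRACT-style: tf, target, evidence) is
reduced to the TFs whose mean target trajectory is itself periodic (at least
three measured targets and a calibrated periodicity score). Phase boundaries
are then read off the targets of a "classification set" of TFs known to peak
at the G1/S, S/G2, G2/M and M/G1 transitions: each group's mean target
signal is spline-interpolated to a 1-minute grid, local maxima are detected
with a +/-10-point dominance rule, peaks are validated against the ordering
of cell-cycle phases, and per-group valid peaks are averaged into transition
times. Only the first cycle after release is classified, because the first
and second cycle may have different phase lengths (alpha-factor and stress
act on the first cycle) while a single global period is assumed elsewhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .matrix import ExpressionMatrix
from .periodicity import GridConfig, fit_periodic_model

PEAK_WINDOW = 10  # 1-min grid points on each side a peak must dominate
MIN_TARGETS = 3

PHASE_ORDER = ("G1/S", "S/G2", "G2/M", "M/G1")


@dataclass
class TFNetwork:
    """Directed TF->target edges plus per-TF periodicity annotations."""

    edges: pd.DataFrame  # columns: tf, target, evidence
    tf_scores: dict[str, float] = field(default_factory=dict)
    tf_target_counts: dict[str, int] = field(default_factory=dict)
    tf_peak_times: dict[str, float] = field(default_factory=dict)
    edge_orientation: pd.DataFrame | None = None  # tf->tf edges among retained

    def __post_init__(self) -> None:
        required = ["tf", "target", "evidence"]
        if list(self.edges.columns[:3]) != required:
            raise ValueError(f"edge list needs columns {required}")

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())

    def targets_of(self, tf: str) -> list[str]:
        return self.edges.loc[self.edges["tf"] == tf, "target"].tolist()

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for tf, target, ev in self.edges.itertuples(index=False):
            g.add_edge(tf, target, evidence=ev)
        return g


@dataclass
class PhaseAnnotation:
    """Ordered first-cycle phase transitions and derived durations."""

    strain: str
    transitions: dict[str, float]  # phase-transition name -> time (min)
    durations: dict[str, float]  # G1, S, G2M (G2 and M merged)
    group_peaks: dict[str, dict[str, list[float]]]  # group -> tf -> valid peaks
    complete: bool
    resolution_min: float = math.nan


def load_tf_network(path: str | Path, evidence: str | None = None) -> TFNetwork:
    """Parse a 3-column TSV edge list; duplicates collapse with a warning."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:2] == ["tf", "target"]:
                continue
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            rows.append(parts)
    df = pd.DataFrame(rows, columns=["tf", "target", "evidence"])
    if evidence is not None:
        df = df[df["evidence"] == evidence]
    n_dup = int(df.duplicated(subset=["tf", "target"]).sum())
    if n_dup:
        warnings.warn(f"collapsed {n_dup} duplicate edges", stacklevel=2)
        df = df.drop_duplicates(subset=["tf", "target"])
    return TFNetwork(df.reset_index(drop=True))


def mean_target_signal(
    net: TFNetwork, tf: str, m: ExpressionMatrix
) -> pd.Series:
    """Arithmetic mean trajectory over the TF's measured targets, per valid
    time point (NaN where no target is valid)."""
    targets = [t for t in net.targets_of(tf) if t in m.gene_ids]
    if not targets:
        raise ValueError(f"TF {tf!r} has no measured target")
    vals = m.values.loc[targets].where(m.mask.loc[targets])
    return vals.mean(axis=0, skipna=True)


def filter_oscillating_tfs(
    net: TFNetwork,
    m: ExpressionMatrix,
    score_cutoff: float,
    min_targets: int = MIN_TARGETS,
    grid: GridConfig | None = None,
) -> TFNetwork:
    """Retain TFs with >= ``min_targets`` measured targets whose mean target
    trajectory scores at or above ``score_cutoff``; orient surviving TF->TF
    edges by target peak times (forward = source's targets peak earlier)."""
    scores: dict[str, float] = {}
    counts: dict[str, int] = {}
    peaks: dict[str, float] = {}
    retained = []
    for tf in net.tfs:
        targets = [t for t in net.targets_of(tf) if t in m.gene_ids]
        counts[tf] = len(targets)
        if len(targets) < min_targets:
            continue
        sig = mean_target_signal(net, tf, m)
        ok = sig.notna()
        fit = fit_periodic_model(
            sig.index.to_numpy(dtype=float)[ok], sig.to_numpy(dtype=float)[ok], grid=grid
        )
        scores[tf] = fit.score
        peaks[tf] = fit.phi_min
        if fit.score >= score_cutoff:
            retained.append(tf)
    if not retained:
        warnings.warn("no TF passes the oscillation filter", stacklevel=2)
    kept = net.edges[net.edges["tf"].isin(retained)].reset_index(drop=True)
    out = TFNetwork(
        kept,
        tf_scores={tf: scores[tf] for tf in retained},
        tf_target_counts={tf: counts[tf] for tf in retained},
        tf_peak_times={tf: peaks[tf] for tf in retained},
    )
    tf_set = set(retained)
    tf_edges = kept[kept["target"].isin(tf_set)]
    if len(tf_edges):
        orient = [
            "forward" if peaks[tf] < peaks[target] else "backward"
            for tf, target in zip(tf_edges["tf"], tf_edges["target"])
        ]
        out.edge_orientation = tf_edges.assign(orientation=orient).reset_index(drop=True)
    return out


def detect_target_peaks(
    times: np.ndarray,
    values: np.ndarray,
    window: int = PEAK_WINDOW,
) -> list[float]:
    """Peak times (min) of a trajectory after natural-cubic-spline
    interpolation onto a 1-minute grid.

    A grid point is a peak iff its value strictly exceeds every one of the
    ``window`` preceding and ``window`` following grid points; points whose
    window is truncated by the boundary are ineligible.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    times, values = times[ok], values[ok]
    if len(times) < 2:
        raise ValueError("need at least 2 valid time points")
    spline = CubicSpline(times, values, bc_type="natural")
    grid = np.arange(math.ceil(times[0]), math.floor(times[-1]) + 1.0)
    y = spline(grid)
    peaks = []
    for i in range(window, len(grid) - window):
        seg = y[i - window : i + window + 1]
        if np.all(y[i] > np.delete(seg, window)):
            peaks.append(float(grid[i]))
    return peaks


def classify_phases(
    groups: list[tuple[str, list[str]]] | tuple,
    net: TFNetwork,
    m: ExpressionMatrix,
    window: int = PEAK_WINDOW,
    strain: str = "",
) -> PhaseAnnotation:
    """Call first-cycle phase-transition times from ordered TF groups.

    ``groups`` is the classification set in cell-cycle order (G1/S, S/G2,
    G2/M, M/G1). Per TF, detected peaks are validated against the previous
    group's assigned first-cycle peaks (strictly later than all of them); the
    earliest valid peak per TF is assigned to the first cycle and assigned
    peaks are averaged into the group's transition time. A group without any
    valid peak leaves the annotation incomplete.
    """
    transitions: dict[str, float] = {}
    group_peaks: dict[str, dict[str, list[float]]] = {}
    prev_max = -math.inf
    complete = True
    for group_name, tfs in groups:
        assigned: list[float] = []
        per_tf: dict[str, list[float]] = {}
        for tf in tfs:
            try:
                sig = mean_target_signal(net, tf, m)
            except ValueError:
                per_tf[tf] = []
                continue
            ok = sig.notna()
            peaks = detect_target_peaks(
                sig.index.to_numpy(dtype=float)[ok],
                sig.to_numpy(dtype=float)[ok],
                window=window,
            )
            valid = [p for p in peaks if p > prev_max]
            per_tf[tf] = valid
            if valid:
                assigned.append(min(valid))
        group_peaks[group_name] = per_tf
        if not assigned:
            complete = False
            break
        transitions[group_name] = float(np.mean(assigned))
        prev_max = max(assigned)
    durations: dict[str, float] = {}
    if complete and len(transitions) == 4:
        t = transitions
        durations = {
            "G1": t["G1/S"],  # cycle start at release, t = 0
            "S": t["S/G2"] - t["G1/S"],
            "G2M": t["M/G1"] - t["S/G2"],
        }
    else:
        complete = False
    return PhaseAnnotation(
        strain=strain,
        transitions=transitions,
        durations=durations,
        group_peaks=group_peaks,
        complete=complete,
    )


def phase_resolution(
    replicate_matrices: list[ExpressionMatrix],
    groups,
    net: TFNetwork,
    window: int = PEAK_WINDOW,
) -> float:
    """Minimum detectable change in phase lengths, from replicate spread.

    Classifies each replicate independently; the resolution is the largest
    range (max - min) of any phase duration across replicates, rounded up to
    the minute. Incomplete replicate annotations are excluded with a warning.
    """
    if len(replicate_matrices) < 2:
        raise ValueError("need at least 2 replicate matrices")
    annotations = []
    for m in replicate_matrices:
        ann = classify_phases(groups, net, m, window=window)
        if ann.complete:
            annotations.append(ann)
        else:
            warnings.warn("excluding incomplete replicate annotation", stacklevel=2)
    if len(annotations) < 2:
        raise ValueError("fewer than 2 complete replicate annotations")
    spread = 0.0
    for phase in ("G1", "S", "G2M"):
        values = [a.durations[phase] for a in annotations]
        spread = max(spread, max(values) - min(values))
    return float(math.ceil(spread))


def network_table(net: TFNetwork) -> pd.DataFrame:
    """Retained-network summary: tf, score, n_targets, peak_time."""
    tfs = sorted(net.tf_scores)
    return pd.DataFrame(
        {
            "tf": tfs,
            "score": [net.tf_scores[t] for t in tfs],
            "n_targets": [net.tf_target_counts[t] for t in tfs],
            "peak_time": [net.tf_peak_times[t] for t in tfs],
        }
    ).set_index("tf")


def phase_table(ann: PhaseAnnotation) -> pd.DataFrame:
    rows = []
    for name in PHASE_ORDER:
        if name in ann.transitions:
            rows.append((ann.strain, name, ann.transitions[name]))
    df = pd.DataFrame(rows, columns=["strain", "transition", "time_min"])
    for phase, dur in ann.durations.items():
        df = pd.concat(
            [df, pd.DataFrame([(ann.strain, f"duration:{phase}", dur)], columns=df.columns)],
            ignore_index=True,
        )
    return df
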