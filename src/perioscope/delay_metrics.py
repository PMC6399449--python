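"""Cross-correlation delay estimation between regulon signals, and bud-index
quantification.

Delays between the mean target signals of the MBF and SBF regulons (or of one
regulon across strains) are estimated as the integer lag, in minutes, at
which the Pearson correlation between the two 1-minute-interpolated signals
is maximal. Sign convention (stated because the literature rarely does): a
positive delay means the *second* signal lags the first, i.e. b(t) ~
a(t - delay). Correlations are computed on the overlapping support without
padding; trajectories are short and non-stationary, so circular correlation
would wrap artefacts around.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

MAX_LAG = 40  # minutes; below one period to avoid locking onto the next peak


@dataclass
class DelayEstimate:
    signal_a: str
    signal_b: str
    delay_min: float  # positive: b later than a
    max_corr: float
    lag_range_min: tuple[float, float]


@dataclass
class BudIndexPoint:
    time_min: float
    index: float
    lower: float
    upper: float
    n_total: int
    valid: bool = True


def regulon_mean_signal(
    targets: list[str], m: ExpressionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Mean 1-min trajectory of a regulon's targets.

    Each gene is first normalized to its temporal mean (log2 fold change;
    a no-op when the matrix is already centred), linearly interpolated to
    1-minute steps over the observed range, then averaged unweighted.
    """
    present = [t for t in targets if t in m.gene_ids]
    if not present:
        raise ValueError("no regulon target measured in the matrix")
    t0, t1 = m.times_min[0], m.times_min[-1]
    grid = np.arange(math.ceil(t0), math.floor(t1) + 1.0)
    rows = []
    for gene in present:
        times, vals = m.gene_trajectory(gene)
        if len(vals) < 2:
            continue
        vals = vals - vals.mean()
        rows.append(np.interp(grid, times, vals))
    if not rows:
        raise ValueError("no regulon target has enough valid points")
    return grid, np.mean(rows, axis=0)


def cross_correlation_delay(
    a: np.ndarray,
    b: np.ndarray,
    max_lag: int = MAX_LAG,
    label_a: str = "a",
    label_b: str = "b",
) -> DelayEstimate:
    """Lag of maximal Pearson correlation between two 1-min signals.

    For each integer lag k in [-max_lag, max_lag] the correlation between
    a(t) and b(t + k) is computed over the overlapping support; lags with a
    zero-variance overlap are skipped. Ties break toward the smallest |k|,
    negative before positive.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = min(len(a), len(b))
    if max_lag >= n / 2:
        raise ValueError("max_lag must be below half the common support")
    best_k, best_r = None, -np.inf
    # visit lags in tie-break order: 0, -1, +1, -2, +2, ...
    order = [0]
    for k in range(1, max_lag + 1):
        order.extend([-k, k])
    for k in order:
        if k >= 0:
            x, y = a[: n - k], b[k:n]
        else:
            x, y = a[-k:n], b[: n + k]
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r > best_r:
            best_k, best_r = k, r
    if best_k is None:
        raise ValueError("all lags had zero-variance overlap")
    return DelayEstimate(
        signal_a=label_a,
        signal_b=label_b,
        delay_min=float(best_k),
        max_corr=best_r,
        lag_range_min=(-float(max_lag), float(max_lag)),
    )


def mbf_sbf_delay(
    strain_matrix: ExpressionMatrix,
    mbf_targets: list[str],
    sbf_targets: list[str],
    max_lag: int = MAX_LAG,
) -> DelayEstimate:
    """Delay of the SBF regulon signal relative to MBF (positive: SBF later)."""
    ga, a = regulon_mean_signal(mbf_targets, strain_matrix)
    gb, b = regulon_mean_signal(sbf_targets, strain_matrix)
    if len(ga) != len(gb) or ga[0] != gb[0]:
        raise ValueError("regulon signals must share the time grid")
    return cross_correlation_delay(a, b, max_lag=max_lag, label_a="MBF", label_b="SBF")


def mutant_vs_wt_mbf_delay(
    mut_matrix: ExpressionMatrix,
    wt_matrix: ExpressionMatrix,
    mbf_targets: list[str],
    max_lag: int = MAX_LAG,
) -> DelayEstimate:
    """Delay of the mutant's MBF signal relative to the wild type's
    (positive: mutant later)."""
    _, wt = regulon_mean_signal(mbf_targets, wt_matrix)
    _, mut = regulon_mean_signal(mbf_targets, mut_matrix)
    return cross_correlation_delay(
        wt, mut, max_lag=max_lag, label_a="WT MBF", label_b="mutant MBF"
    )


def bud_index(counts: pd.DataFrame) -> tuple[list[BudIndexPoint], float]:
    """Budded fraction per time point with uncertainty bounds.

    Large daughter cells that could not be told apart from buds are split
    equally between the cell and bud groups: index = (buds + large/2)/total.
    The lower bound counts all of them as cells, the upper bound as buds.
    Returns the points and the time of the maximal index.
    """
    required = {"time_min", "cells", "buds", "large"}
    if not required.issubset(counts.columns):
        raise ValueError(f"bud-count table needs columns {sorted(required)}")
    points = []
    for row in counts.itertuples(index=False):
        total = int(row.cells) + int(row.buds) + int(row.large)
        if min(row.cells, row.buds, row.large) < 0:
            raise ValueError("bud counts must be non-negative")
        if total == 0:
            points.append(BudIndexPoint(float(row.time_min), math.nan, math.nan, math.nan, 0, valid=False))
            continue
        points.append(
            BudIndexPoint(
                time_min=float(row.time_min),
                index=(row.buds + row.large / 2.0) / total,
                lower=row.buds / total,
                upper=(row.buds + row.large) / total,
                n_total=total,
            )
        )
    valid = [p for p in points if p.valid]
    if not valid:
        raise ValueError("no valid bud-count time point")
    argmax_time = max(valid, key=lambda p: p.index).time_min
    return points, argmax_time
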