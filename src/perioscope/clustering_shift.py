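"""Trajectory clustering and mutant-vs-wild-type peak-time shift analysis.

k-means groups log2 fold-change trajectories into expression waves; clusters
whose mean trajectory itself passes the periodicity-score cutoff are flagged
oscillatory and ordered by peak time. Peak-time shifts between two strains
are summarized by a robust first-degree lowess curve of mutant peak time
against wild-type peak time: points on the bisecting line have conserved
timing, a vertical offset is an onset delay, and a local slope below one
marks phases through which the mutant progresses more slowly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .matrix import ExpressionMatrix
from .periodicity import CalibrationResult, GridConfig, fit_periodic_model

DEFAULT_K = 12  # expected: ~5 oscillatory waves + alpha-response + background
LOWESS_SPAN = 0.2
LOWESS_ROBUST_ITERS = 5


@dataclass
class ClusterAssignment:
    k: int
    labels: pd.Series  # gene_id -> cluster index in [1, k]
    centroids: pd.DataFrame  # k rows, time columns
    oscillatory_flags: list[bool] | None = None
    peak_order: list[int] | None = None  # oscillatory clusters by centroid phi
    centroid_phi: dict[int, float] | None = None


@dataclass
class ShiftCurve:
    wt_peaks: np.ndarray
    mut_peaks: np.ndarray
    smoothed: tuple[np.ndarray, np.ndarray]  # (x sorted, y fitted)
    mean_delay: float
    local_slope: np.ndarray


def kmeans_trajectories(
    m: ExpressionMatrix, k: int = DEFAULT_K, seed: int = 0, n_restarts: int = 10
) -> ClusterAssignment:
    """Cluster mask-complete trajectories with k-means (best of restarts)."""
    m.require_stage("log2fc", "kmeans_trajectories")
    complete = m.mask.all(axis=1)
    X = m.values.loc[complete].to_numpy(dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} complete genes")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X) + 1
    centroids = pd.DataFrame(
        km.cluster_centers_, index=np.arange(1, k + 1), columns=m.values.columns
    )
    return ClusterAssignment(
        k=k,
        labels=pd.Series(labels, index=m.values.index[complete]),
        centroids=centroids,
    )


def flag_oscillatory_clusters(
    c: ClusterAssignment,
    cal: CalibrationResult,
    grid: GridConfig | None = None,
) -> ClusterAssignment:
    """Flag clusters whose centroid trajectory scores at or above the
    calibrated periodicity cutoff; order flagged clusters by centroid peak
    time."""
    times = c.centroids.columns.to_numpy(dtype=float)
    flags, phis = [], {}
    for cid in c.centroids.index:
        y = c.centroids.loc[cid].to_numpy(dtype=float)
        fit = fit_periodic_model(times, y - y.mean(), grid=grid)
        flags.append(fit.score >= cal.score_cutoff)
        phis[int(cid)] = fit.phi_min
    c.oscillatory_flags = flags
    c.centroid_phi = phis
    osc = [int(cid) for cid, f in zip(c.centroids.index, flags) if f]
    c.peak_order = sorted(osc, key=lambda cid: phis[cid])
    return c


def align_mutant_phases(
    wt_phi: np.ndarray, mut_phi: np.ndarray, period: float
) -> np.ndarray:
    """Map each mutant peak time into [wt - period/2, wt + period/2).

    Peak times are circular within a cycle; the shift plot is planar, so
    wrap-around differences near the cycle boundary are folded back before
    smoothing.
    """
    wt_phi = np.asarray(wt_phi, dtype=float)
    mut_phi = np.asarray(mut_phi, dtype=float)
    shift = np.round((wt_phi - mut_phi) / period)
    return mut_phi + period * shift


def lowess_shift(
    wt_phi: np.ndarray,
    mut_phi: np.ndarray,
    span: float = LOWESS_SPAN,
    robust_iters: int = LOWESS_ROBUST_ITERS,
) -> ShiftCurve:
    """Robust local linear regression of mutant peak time on wild-type peak
    time (tricube weights over a ``span`` fraction window, ``robust_iters``
    bisquare reweighting passes)."""
    wt_phi = np.asarray(wt_phi, dtype=float)
    mut_phi = np.asarray(mut_phi, dtype=float)
    if len(wt_phi) != len(mut_phi):
        raise ValueError("peak-time arrays must have equal length")
    if len(wt_phi) < 10:
        raise ValueError("need at least 10 peak-time pairs")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if span * len(wt_phi) < 2:
        raise ValueError("span window holds fewer than 2 points")
    fitted = _sm_lowess(mut_phi, wt_phi, frac=span, it=robust_iters, return_sorted=True)
    # one fitted y per x: collapse duplicate abscissae so the curve is a function
    x, first = np.unique(fitted[:, 0], return_index=True)
    y = fitted[first, 1]
    mean_delay = float(np.mean(y - x))
    slope = np.gradient(y, x) if len(x) > 1 else np.ones_like(y)
    return ShiftCurve(
        wt_peaks=wt_phi,
        mut_peaks=mut_phi,
        smoothed=(x, y),
        mean_delay=mean_delay,
        local_slope=slope,
    )


def shift_curve_between(
    wt_fits: pd.DataFrame,
    mut_fits: pd.DataFrame,
    span: float = LOWESS_SPAN,
    robust_iters: int = LOWESS_ROBUST_ITERS,
) -> ShiftCurve:
    """Shift curve over genes passing the oscillation filter in both strains.

    Expects fit tables from :func:`perioscope.periodicity.fits_to_frame`;
    mutant peak times are unwrapped against the wild type using each gene's
    wild-type period before smoothing.
    """
    shared = wt_fits.index[wt_fits["pass"].astype(bool)].intersection(
        mut_fits.index[mut_fits["pass"].astype(bool)]
    )
    wt_phi = wt_fits.loc[shared, "phi"].to_numpy(dtype=float)
    mut_phi = mut_fits.loc[shared, "phi"].to_numpy(dtype=float)
    periods = wt_fits.loc[shared, "lambda"].to_numpy(dtype=float)
    mut_aligned = np.array(
        [
            align_mutant_phases(w, mu, lam)
            for w, mu, lam in zip(wt_phi, mut_phi, periods)
        ]
    ).ravel()
    return lowess_shift(wt_phi, mut_aligned, span=span, robust_iters=robust_iters)
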