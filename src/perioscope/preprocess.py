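"""Raw-count processing: depth filtering, expression filtering, total-count
normalization, replicate merging and log2 fold-change to each gene's
temporal mean.

The fixed pipeline order is depth drop -> low-expression filter -> total
normalization -> replicate merge -> log2 fold change; each step checks the
stage of its input and refuses to re-run on its own output.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

MIN_COLUMN_TOTAL = 7e4  # reads; columns below this are dropped
MIN_GENE_READS = 10  # total reads over the course; strictly-below genes go
MIN_REPLICATE_CORR = 0.9


def drop_low_depth_timepoints(
    m: ExpressionMatrix, min_total: float = MIN_COLUMN_TOTAL
) -> ExpressionMatrix:
    """Invalidate sampling times whose total read count is below ``min_total``.

    The columns stay on the time grid (masked) so that grids remain aligned
    across strains.
    """
    m.require_stage("raw_counts", "drop_low_depth_timepoints")
    out = m.copy()
    totals = out.column_totals()
    bad = totals[totals < min_total].index
    if len(bad) == len(totals):
        raise ValueError(
            f"all time points fall below the depth threshold {min_total:g}"
        )
    if len(bad):
        logger.info("dropping %d low-depth time points: %s", len(bad), list(bad))
        out.mask.loc[:, bad] = False
    return out


def filter_low_expression(
    m: ExpressionMatrix, min_reads: float = MIN_GENE_READS
) -> ExpressionMatrix:
    """Remove genes whose total valid reads over the course are strictly below
    ``min_reads``; survivor order is preserved."""
    m.require_stage("raw_counts", "filter_low_expression")
    totals = m.values.where(m.mask, 0.0).sum(axis=1)
    keep = totals >= min_reads
    if not keep.any():
        raise ValueError(f"no gene reaches {min_reads:g} total reads")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("excluding %d genes below %g reads", dropped, min_reads)
    return ExpressionMatrix(
        m.values.loc[keep].copy(), stage="raw_counts", mask=m.mask.loc[keep].copy()
    )


def normalize_total(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide every valid column by its total so column sums become 1."""
    m.require_stage("raw_counts", "normalize_total")
    out = m.copy()
    totals = out.column_totals()
    col_valid = out.mask.any(axis=0)
    if np.any((totals[col_valid] <= 0).to_numpy()):
        raise ValueError(
            "zero-total valid column encountered; drop low-depth time points first"
        )
    vals = out.values.astype(float)
    for col in vals.columns:
        if col_valid[col]:
            vals[col] = vals[col] / totals[col]
    return ExpressionMatrix(vals, stage="depth_normalized", mask=out.mask)


def merge_replicates(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    min_corr: float = MIN_REPLICATE_CORR,
) -> ExpressionMatrix:
    """Average two replicates cell-wise after a reproducibility check.

    The check computes the Pearson correlation of per-gene median expression
    between the replicates and warns (does not fail) when it falls below
    ``min_corr``.
    """
    if a.stage != b.stage:
        raise ValueError("replicates must be at the same processing stage")
    shared = a.gene_ids.intersection(b.gene_ids)
    if len(shared) == 0:
        raise ValueError("replicates share no genes")
    av, bv = a.values.loc[shared], b.values.loc[shared]
    am, bm = a.mask.loc[shared], b.mask.loc[shared]
    med_a = av.where(am).median(axis=1)
    med_b = bv.where(bm).median(axis=1)
    ok = med_a.notna() & med_b.notna()
    corr = float(stats.pearsonr(med_a[ok], med_b[ok])[0]) if ok.sum() >= 2 else np.nan
    if np.isnan(corr) or corr < min_corr:
        warnings.warn(
            f"replicate median-expression correlation {corr:.3f} below {min_corr}",
            stacklevel=2,
        )
    merged = (av + bv) / 2.0
    mask = am & bm
    stage = a.stage
    if stage == "raw_counts":
        # means of integer counts can be half-integral; keep the raw stage
        # contract by rounding to the nearest count
        merged = merged.round()
    return ExpressionMatrix(merged, stage=stage, mask=mask)


def log2fc_to_temporal_mean(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per gene: log2 of the normalized values, centred to the gene's own
    temporal mean of log2 values (so every gene's valid values average 0).

    A pseudo-fraction of half the smallest positive value guards zeros.
    Genes with fewer than two valid points are masked out entirely.
    """
    m.require_stage("depth_normalized", "log2fc_to_temporal_mean")
    vals = m.values.to_numpy(dtype=float).copy()
    mask = m.mask.to_numpy().copy()
    pos = vals[mask & (vals > 0)]
    pseudo = 0.5 * pos.min() if len(pos) else 1e-12
    vals = np.where(mask, vals + pseudo, np.nan)
    logv = np.log2(vals)
    n_valid = mask.sum(axis=1)
    few = n_valid < 2
    if few.any():
        logger.info("flagging %d genes with <2 valid points", int(few.sum()))
        mask[few] = False
    with np.errstate(invalid="ignore"):
        row_mean = np.nanmean(np.where(mask, logv, np.nan), axis=1, keepdims=True)
    centred = np.where(mask, logv - row_mean, 0.0)
    out = pd.DataFrame(centred, index=m.gene_ids, columns=m.values.columns)
    return ExpressionMatrix(out, stage="log2fc", mask=pd.DataFrame(mask, index=m.gene_ids, columns=m.values.columns))


def preprocess_counts(
    a: ExpressionMatrix,
    b: ExpressionMatrix | None = None,
    min_total: float = MIN_COLUMN_TOTAL,
    min_reads: float = MIN_GENE_READS,
    min_corr: float = MIN_REPLICATE_CORR,
) -> ExpressionMatrix:
    """Full pipeline: depth drop -> expression filter -> normalize ->
    (optional replicate merge) -> log2 fold change to temporal mean."""

    def upstream(m: ExpressionMatrix) -> ExpressionMatrix:
        m = drop_low_depth_timepoints(m, min_total)
        m = filter_low_expression(m, min_reads)
        return normalize_total(m)

    na = upstream(a)
    if b is not None:
        nb = upstream(b)
        shared = na.gene_ids.intersection(nb.gene_ids)
        na = ExpressionMatrix(na.values.loc[shared], na.stage, na.mask.loc[shared])
        nb = ExpressionMatrix(nb.values.loc[shared], nb.stage, nb.mask.loc[shared])
        na = merge_replicates(na, nb, min_corr)
    return log2fc_to_temporal_mean(na)
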