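"""Gene-by-time expression matrices with validity masks and processing stages.

The container tracks which processing stage a matrix is in (``raw_counts``,
``depth_normalized`` or ``log2fc``) so that pipeline steps can refuse to run
out of order, and carries a per-cell validity mask so that dropped time points
stay on the time grid (keeping grids aligned across strains) instead of being
deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

STAGES = ("raw_counts", "depth_normalized", "log2fc")


@dataclass
class ExpressionMatrix:
    """Genes x time-points expression values.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sampling time in minutes
        (integers, strictly increasing).
    stage : str
        One of ``raw_counts``, ``depth_normalized``, ``log2fc``.
    mask : pandas.DataFrame, optional
        Boolean validity per cell; defaults to all-valid. Invalid cells are
        ignored by downstream statistics.
    """

    values: pd.DataFrame
    stage: str = "raw_counts"
    mask: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        times = np.asarray(self.values.columns, dtype=float)
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError("time columns must be strictly increasing")
        self.values = self.values.copy()
        self.values.columns = times.astype(int)
        if self.mask is None:
            self.mask = pd.DataFrame(
                True, index=self.values.index, columns=self.values.columns
            )
        else:
            self.mask = self.mask.astype(bool)
            self.mask.columns = self.values.columns
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")
        if self.stage == "raw_counts":
            vals = self.values.to_numpy(dtype=float)[self.mask.to_numpy()]
            if len(vals) and (np.any(vals < 0) or np.any(vals != np.round(vals))):
                raise ValueError("raw_counts stage requires non-negative integers")

    # -- accessors --------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def times_min(self) -> np.ndarray:
        return self.values.columns.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.stage, self.mask.copy())

    def gene_trajectory(self, gene_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Valid (times, values) for one gene."""
        row = self.values.loc[gene_id]
        ok = self.mask.loc[gene_id].to_numpy()
        return self.times_min[ok], row.to_numpy(dtype=float)[ok]

    def column_totals(self) -> pd.Series:
        masked = self.values.where(self.mask, 0.0)
        return masked.sum(axis=0)

    def require_stage(self, stage: str, op: str) -> None:
        if self.stage != stage:
            raise ValueError(
                f"{op} expects a {stage!r} matrix but got stage {self.stage!r}"
            )

    # -- TSV dialect -------------------------------------------------------
    # First column `gene_id`, remaining columns headed by integer minutes.
    # Invalid cells are written as NA. Stage goes to a key=value sidecar.

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        out = self.values.where(self.mask, other=np.nan)
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", na_rep="NA")
        meta = path.with_suffix(path.suffix + ".meta")
        meta.write_text(f"stage={self.stage}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, stage: str | None = None) -> "ExpressionMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="gene_id", na_values=["NA"])
        if stage is None:
            meta = path.with_suffix(path.suffix + ".meta")
            stage = "raw_counts"
            if meta.exists():
                for line in meta.read_text().splitlines():
                    key, _, val = line.partition("=")
                    if key.strip() == "stage":
                        stage = val.strip()
        mask = df.notna()
        return cls(df.fillna(0.0), stage=stage, mask=mask)
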