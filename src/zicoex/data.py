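"""Per-gene-pair data container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenePairData"]


@dataclass
class GenePairData:
    """Paired count vectors for one gene pair plus per-cell metadata.

    y1, y2      non-negative integer counts of the two genes, one entry per cell
    patient     patient / subject label per cell (grouping factor)
    covariates  per-cell covariate table (e.g. a 0/1 or categorical condition)
    depth       total sequencing depth S_i per cell (positive); enters the
                mean predictors as the offset log(S_i)
    cell_ids    optional cell barcodes, used in error messages
    """

    y1: np.ndarray
    y2: np.ndarray
    patient: np.ndarray
    covariates: pd.DataFrame
    depth: np.ndarray
    cell_ids: np.ndarray | None = None
    gene_names: tuple[str, str] = ("gene1", "gene2")

    def __post_init__(self):
        self.y1 = np.asarray(self.y1)
        self.y2 = np.asarray(self.y2)
        self.patient = np.asarray(self.patient)
        self.depth = np.asarray(self.depth, dtype=float)
        if not isinstance(self.covariates, pd.DataFrame):
            self.covariates = pd.DataFrame(self.covariates)
        n = len(self.y1)
        for name, arr in (("y2", self.y2), ("patient", self.patient),
                          ("depth", self.depth)):
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if len(self.covariates) != n:
            raise ValueError(
                f"covariates has {len(self.covariates)} rows, expected {n}")
        for name, y in (("y1", self.y1), ("y2", self.y2)):
            if np.any(y < 0) or np.any(y != np.floor(y)):
                raise ValueError(f"{name} must contain non-negative integers")
        if np.any(~np.isfinite(self.depth)) or np.any(self.depth <= 0):
            raise ValueError("depth must be positive and finite")
        if self.cell_ids is not None:
            self.cell_ids = np.asarray(self.cell_ids)
            if len(self.cell_ids) != n:
                raise ValueError("cell_ids length mismatch")

    @property
    def n_cells(self) -> int:
        return len(self.y1)

    def cell_label(self, i: int) -> str:
        if self.cell_ids is not None:
            return str(self.cell_ids[i])
        return f"cell #{i}"

    def subset(self, index) -> "GenePairData":
        index = np.asarray(index)
        return GenePairData(
            y1=self.y1[index], y2=self.y2[index], patient=self.patient[index],
            covariates=self.covariates.iloc[index].reset_index(drop=True),
            depth=self.depth[index],
            cell_ids=None if self.cell_ids is None else self.cell_ids[index],
            gene_names=self.gene_names)
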