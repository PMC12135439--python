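"""Expression data container with per-sample intervention annotation.

A dataset is a samples x genes matrix of expression levels plus, for each
sample, the identity of the knocked-out gene (or none) and the value it was
clamped to.  Series and time indices record which perturbation time series
a sample came from.  Serialised as a tab-separated table with gene-name
columns and an ``intervention`` column holding a gene name or ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "NO_INTERVENTION"]

NO_INTERVENTION = -1


@dataclass
class ExpressionDataset:
    """samples x genes expression values with intervention annotation.

    ``interventions[s]`` is the knocked-out gene index for sample ``s`` or
    ``NO_INTERVENTION`` (-1); ``clamp_values[s]`` is the value the target
    was held at (0 for a knockout).
    """

    values: np.ndarray
    interventions: np.ndarray | None = None
    clamp_values: np.ndarray | None = None
    series_id: np.ndarray | None = None
    time_index: np.ndarray | None = None
    gene_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes matrix")
        n_rows, n_genes = self.values.shape
        if self.interventions is None:
            self.interventions = np.full(n_rows, NO_INTERVENTION, dtype=int)
        else:
            self.interventions = np.asarray(self.interventions, dtype=int)
        if self.clamp_values is None:
            self.clamp_values = np.zeros(n_rows)
        else:
            self.clamp_values = np.asarray(self.clamp_values, dtype=float)
        for name in ("interventions", "clamp_values", "series_id",
                     "time_index"):
            arr = getattr(self, name)
            if arr is not None and np.asarray(arr).shape != (n_rows,):
                raise ValueError(f"{name} must have one entry per sample")
        if np.any(self.interventions >= n_genes) or \
                np.any(self.interventions < NO_INTERVENTION):
            raise ValueError("intervention targets out of range")
        if self.gene_names is not None:
            self.gene_names = tuple(self.gene_names)
            if len(self.gene_names) != n_genes:
                raise ValueError("gene_names length must equal gene count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_interventional(self) -> int:
        return int(np.sum(self.interventions != NO_INTERVENTION))

    def observational_rows(self) -> np.ndarray:
        return np.flatnonzero(self.interventions == NO_INTERVENTION)

    def names(self) -> tuple[str, ...]:
        return self.gene_names or tuple(f"G{k + 1}"
                                        for k in range(self.n_genes))

    # -- combination ------------------------------------------------------

    @staticmethod
    def concat(parts: Sequence["ExpressionDataset"]) -> "ExpressionDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        n_genes = parts[0].n_genes
        if any(p.n_genes != n_genes for p in parts):
            raise ValueError("gene counts differ")

        def cat(attr, fallback):
            cols = []
            for p in parts:
                arr = getattr(p, attr)
                cols.append(np.asarray(arr) if arr is not None
                            else np.full(p.n_samples, fallback))
            return np.concatenate(cols)

        return ExpressionDataset(
            np.vstack([p.values for p in parts]),
            interventions=cat("interventions", NO_INTERVENTION),
            clamp_values=cat("clamp_values", 0.0),
            series_id=cat("series_id", -1),
            time_index=cat("time_index", -1),
            gene_names=parts[0].gene_names,
        )

    # -- I/O --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        names = self.names()
        df = pd.DataFrame(self.values, columns=list(names))
        df["intervention"] = ["none" if t == NO_INTERVENTION else names[t]
                              for t in self.interventions]
        if self.series_id is not None:
            df["series"] = np.asarray(self.series_id)
        if self.time_index is not None:
            df["time"] = np.asarray(self.time_index)
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionDataset":
        meta_cols = [c for c in ("intervention", "series", "time")
                     if c in df.columns]
        genes = [c for c in df.columns if c not in meta_cols]
        lookup = {g: k for k, g in enumerate(genes)}
        if "intervention" in df.columns:
            iv = np.array([NO_INTERVENTION if t in ("none", "", None)
                           else lookup[t] for t in df["intervention"]])
        else:
            iv = None
        return cls(
            df[genes].to_numpy(dtype=float),
            interventions=iv,
            series_id=df["series"].to_numpy() if "series" in df else None,
            time_index=df["time"].to_numpy() if "time" in df else None,
            gene_names=tuple(genes),
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionDataset":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
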