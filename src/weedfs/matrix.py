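"""Gene-expression matrix container.

Genes are rows, samples are columns (GCT convention). Missing cells are
stored as NaN in ``values`` and flagged in ``missing_mask``; the mask is
authoritative so downstream steps never have to guess whether a NaN is a
measurement or a hole.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np


@dataclasses.dataclass
class ExpressionMatrix:
    """A genes x samples real matrix with identifiers, labels and a missing mask.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_genes, n_samples)``. Missing entries are NaN.
    gene_ids
        One identifier per row. Duplicates are allowed (pre-collapse state).
    sample_ids
        One unique identifier per column.
    labels
        Optional per-sample class label; when present, exactly two distinct
        values must occur.
    missing_mask
        Boolean matrix aligned with ``values``; True marks a missing cell.
        Defaults to ``isnan(values)``.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray | None = None
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.array(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        n_genes, n_samples = self.values.shape
        if n_genes == 0 or n_samples == 0:
            raise ValueError("empty expression matrix")
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != row count {n_genes}"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"sample_ids length {len(self.sample_ids)} != column count {n_samples}"
            )
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("duplicate sample identifiers are not allowed")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.array(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape must match values shape")
        self.values[self.missing_mask] = np.nan
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n_samples,):
                raise ValueError("labels length must equal sample count")
            if len(set(self.labels.tolist())) != 2:
                raise ValueError("labels must contain exactly two distinct classes")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def class_names(self) -> list:
        """The two class labels in order of first appearance."""
        if self.labels is None:
            raise ValueError("matrix carries no labels")
        seen: list = []
        for lab in self.labels.tolist():
            if lab not in seen:
                seen.append(lab)
        return seen

    def label_codes(self, positive_label=None) -> np.ndarray:
        """Integer 0/1 codes; the positive class (default: second by first
        appearance) maps to 1."""
        names = self.class_names
        if positive_label is None:
            positive_label = names[-1]
        if positive_label not in names:
            raise ValueError(f"unknown positive label {positive_label!r}")
        return (self.labels == positive_label).astype(int)

    # -- copies and views ----------------------------------------------
    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            labels=None if self.labels is None else self.labels.copy(),
            missing_mask=self.missing_mask.copy(),
        )

    def subset_genes(self, keep: Sequence[int] | np.ndarray) -> "ExpressionMatrix":
        """Row subset by integer indices or a boolean mask; order preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            if keep.shape != (self.n_genes,):
                raise ValueError("boolean gene mask length must equal gene count")
            idx = np.flatnonzero(keep)
        else:
            idx = keep.astype(int)
        return ExpressionMatrix(
            values=self.values[idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            labels=None if self.labels is None else self.labels.copy(),
            missing_mask=self.missing_mask[idx],
        )

    def subset_samples(self, idx: Sequence[int] | np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            values=self.values[:, idx],
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx],
            missing_mask=self.missing_mask[:, idx],
        )

    def sample_matrix(self) -> np.ndarray:
        """Samples x genes array (the orientation classifiers expect)."""
        return np.ascontiguousarray(self.values.T)
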