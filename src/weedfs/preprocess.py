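"""Preprocessing cascade for expression matrices.

Steps: log transformation (symmetrises skewed raw intensities), replicate
collapsing (duplicate gene IDs averaged), mean imputation of missing cells,
flat-pattern filtering (near-constant genes removed) and per-gene
standardization to mean 0 / SD 1. The default order runs the flat filter
before standardization so zero-variance rows never reach the divide.

Standardization uses the population SD (divisor n), which makes the
mean-0/SD-1 postcondition exact. Centering is per gene; per-sample centering
is a deliberate non-choice (gene-wise scaling is what removes scale variance
among features when genes are the features).
"""
from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .matrix import ExpressionMatrix

STEP_NAMES = ("log", "collapse", "impute", "flat_filter", "standardize")
DEFAULT_ORDER = ["log", "collapse", "impute", "flat_filter", "standardize"]


@dataclasses.dataclass
class PreprocessConfig:
    do_log: bool = True
    log_base: float = 2.0
    log_shift: float = 1.0
    collapse_replicates: bool = True
    impute: bool = True
    standardize: bool = True
    flat_filter: bool = True
    flat_metric: str = "variance"  # or "range"
    flat_threshold: float = 1e-6
    step_order: list[str] = dataclasses.field(default_factory=lambda: list(DEFAULT_ORDER))

    def validate(self) -> None:
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")
        if self.log_shift < 0:
            raise ValueError("log_shift must be >= 0")
        if self.flat_threshold < 0:
            raise ValueError("flat_threshold must be >= 0")
        if self.flat_metric not in ("variance", "range"):
            raise ValueError("flat_metric must be 'variance' or 'range'")
        unknown = set(self.step_order) - set(STEP_NAMES)
        if unknown:
            raise ValueError(f"unknown step names in step_order: {sorted(unknown)}")
        enabled = set(self.enabled_steps())
        ordered = [s for s in self.step_order if s in enabled]
        if set(ordered) != enabled or len(ordered) != len(set(ordered)):
            raise ValueError("step_order must contain each enabled step exactly once")

    def enabled_steps(self) -> list[str]:
        flags = {
            "log": self.do_log,
            "collapse": self.collapse_replicates,
            "impute": self.impute,
            "flat_filter": self.flat_filter,
            "standardize": self.standardize,
        }
        return [s for s in STEP_NAMES if flags[s]]


def log_transform(m: ExpressionMatrix, base: float = 2.0, shift: float = 1.0) -> ExpressionMatrix:
    """Replace each non-missing value v by log_base(v + shift)."""
    out = m.copy()
    obs = ~out.missing_mask
    shifted = out.values + shift
    bad = obs & ~(shifted > 0)
    if bad.any():
        gi, sj = np.argwhere(bad)[0]
        raise ValueError(
            f"log transform undefined for gene {m.gene_ids[gi]!r}, sample "
            f"{m.sample_ids[sj]!r}: value {m.values[gi, sj]} + shift {shift} <= 0"
        )
    out.values[obs] = np.log(shifted[obs]) / math.log(base)
    return out


def collapse_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Average rows sharing a gene ID (mean over non-missing replicates).

    First-occurrence order is preserved; a cell stays missing only if it is
    missing in every replicate.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(m.gene_ids):
        if g not in groups:
            groups[g] = []
            order.append(g)
        groups[g].append(i)
    if all(len(v) == 1 for v in groups.values()):
        return m.copy()
    values = np.empty((len(order), m.n_samples))
    mask = np.empty((len(order), m.n_samples), dtype=bool)
    for r, g in enumerate(order):
        rows = groups[g]
        block = m.values[rows]
        obs = ~m.missing_mask[rows]
        cnt = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            values[r] = np.where(cnt > 0, np.nansum(np.where(obs, block, 0.0), axis=0) / np.maximum(cnt, 1), np.nan)
        mask[r] = cnt == 0
    return ExpressionMatrix(
        values=values,
        gene_ids=order,
        sample_ids=list(m.sample_ids),
        labels=None if m.labels is None else m.labels.copy(),
        missing_mask=mask,
    )


def impute_missing(m: ExpressionMatrix) -> ExpressionMatrix:
    """Fill each missing cell with the mean of its gene's observed values."""
    out = m.copy()
    if not out.missing_mask.any():
        return out
    obs = ~out.missing_mask
    n_obs = obs.sum(axis=1)
    if (n_obs == 0).any():
        g = m.gene_ids[int(np.argmax(n_obs == 0))]
        raise ValueError(f"gene {g!r} has no observed values; cannot mean-impute")
    row_mean = np.nansum(np.where(obs, out.values, 0.0), axis=1) / n_obs
    fill = np.broadcast_to(row_mean[:, None], out.values.shape)
    out.values[out.missing_mask] = fill[out.missing_mask]
    out.missing_mask = np.zeros_like(out.missing_mask)
    return out


def standardize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene row to mean 0, population SD 1."""
    if m.missing_mask.any():
        raise ValueError("standardize requires a complete matrix; impute first")
    out = m.copy()
    mean = out.values.mean(axis=1, keepdims=True)
    sd = out.values.std(axis=1, keepdims=True)  # population SD (divisor n)
    if (sd == 0).any():
        g = m.gene_ids[int(np.argmax(sd[:, 0] == 0))]
        raise ValueError(
            f"gene {g!r} has zero SD; run the flat-pattern filter before standardizing"
        )
    out.values = (out.values - mean) / sd
    return out


def flat_pattern_filter(
    m: ExpressionMatrix, metric: str = "variance", threshold: float = 1e-6
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose dispersion (variance or max-min range) is < threshold.

    Returns the filtered matrix and the removed gene IDs, in original order.
    """
    if m.missing_mask.any():
        raise ValueError("flat_pattern_filter requires a complete matrix; impute first")
    if metric == "variance":
        disp = m.values.var(axis=1)
    elif metric == "range":
        disp = m.values.max(axis=1) - m.values.min(axis=1)
    else:
        raise ValueError("metric must be 'variance' or 'range'")
    keep = disp >= threshold
    if not keep.any():
        raise ValueError("flat-pattern filter would remove every gene")
    removed = [g for g, k in zip(m.gene_ids, keep) if not k]
    return m.subset_genes(keep), removed


@dataclasses.dataclass
class StepRecord:
    step: str
    genes_in: int
    genes_out: int
    removed_gene_ids: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class PreprocessResult:
    matrix: ExpressionMatrix
    provenance: list[StepRecord]

    def provenance_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps([dataclasses.asdict(r) for r in self.provenance], indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def run_preprocess(m: ExpressionMatrix, cfg: PreprocessConfig | None = None) -> PreprocessResult:
    """Apply the enabled steps in ``cfg.step_order`` with per-step provenance."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    enabled = set(cfg.enabled_steps())
    current = m
    records: list[StepRecord] = []
    for step in cfg.step_order:
        if step not in enabled:
            continue
        n_in = current.n_genes
        removed: list[str] = []
        if step == "log":
            current = log_transform(current, cfg.log_base, cfg.log_shift)
        elif step == "collapse":
            current = collapse_replicates(current)
        elif step == "impute":
            current = impute_missing(current)
        elif step == "flat_filter":
            current, removed = flat_pattern_filter(current, cfg.flat_metric, cfg.flat_threshold)
        elif step == "standardize":
            current = standardize(current)
        records.append(
            StepRecord(step=step, genes_in=n_in, genes_out=current.n_genes, removed_gene_ids=removed)
        )
    return PreprocessResult(matrix=current, provenance=records)
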