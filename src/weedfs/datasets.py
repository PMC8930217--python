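"""Synthetic two-class expression data with planted differential genes.

The generator emulates a small two-class microarray study: a handful of
informative genes carry a standardized between-class mean shift, everything
else is class-independent noise around a gene-specific baseline. Optional
contamination (duplicate gene IDs, missing cells, near-constant rows) plants
exactly the defects the preprocessing cascade is meant to repair, with the
ground-truth informative set recorded so selection quality can be scored.

Class model: gene g in class c is Normal(mu_g + s_g * effect * [c == class2],
noise_sd) on the log2 scale, with the shift sign s_g alternating across
informative genes so no single global mean filter can recover the set.
``raw_scale`` exponentiates base 2 to mimic skewed raw intensities.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .matrix import ExpressionMatrix

#: default shape mirrors a classic two-class prostate microarray study:
#: 52 tumor + 50 normal samples over 2135 genes.
DEFAULT_N_GENES = 2135
DEFAULT_SAMPLES_PER_CLASS = (52, 50)
CLASS_NAMES = ("tumor", "normal")


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    ``effect_size`` is the standardized mean shift (in units of ``noise_sd``)
    of informative genes between the two classes. Contamination counts
    default to zero: a default-constructed spec yields a clean matrix of the
    requested shape.
    """

    n_genes: int = DEFAULT_N_GENES
    n_informative: int = 50
    n_samples_per_class: tuple[int, int] = DEFAULT_SAMPLES_PER_CLASS
    effect_size: float = 2.0
    noise_sd: float = 1.0
    frac_missing: float = 0.0
    n_replicate_ids: int = 0
    n_flat_genes: int = 0
    raw_scale: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (0 <= self.n_informative <= self.n_genes):
            raise ValueError("n_informative must satisfy 0 <= n_informative <= n_genes")
        if self.n_flat_genes < 0 or self.n_flat_genes + self.n_informative > self.n_genes:
            raise ValueError("n_flat_genes must satisfy n_flat_genes + n_informative <= n_genes")
        if any(n < 1 for n in self.n_samples_per_class):
            raise ValueError("n_samples_per_class entries must be >= 1")
        if not (0.0 <= self.frac_missing <= 0.5):
            raise ValueError("frac_missing must lie in [0, 0.5]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_replicate_ids < 0 or self.n_replicate_ids > self.n_genes:
            raise ValueError("n_replicate_ids must satisfy 0 <= n_replicate_ids <= n_genes")

    @property
    def has_contamination(self) -> bool:
        return (
            self.frac_missing > 0 or self.n_replicate_ids > 0 or self.n_flat_genes > 0
        )


@dataclasses.dataclass
class LabeledDataset:
    """A generated matrix plus the ground-truth informative gene IDs."""

    matrix: ExpressionMatrix
    truth_informative: set[str]
    spec: SyntheticSpec

    def __post_init__(self) -> None:
        if not self.truth_informative <= set(self.matrix.gene_ids):
            raise ValueError("truth_informative must be a subset of the gene IDs")


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Draw a labeled two-class matrix; deterministic for a fixed seed.

    Informative genes occupy the first ``n_informative`` rows (row order is
    not informative to downstream code: selection operates on IDs/masks and
    never sees the truth set). If the spec requests contamination the clean
    matrix is passed through :func:`inject_contamination`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_samples_per_class
    n_samples = n1 + n2
    baseline = rng.normal(7.0, 1.5, size=spec.n_genes)
    values = rng.normal(
        baseline[:, None], spec.noise_sd, size=(spec.n_genes, n_samples)
    )
    # planted shift: class 1 ("tumor", first n1 columns) moves by
    # +/- effect_size * noise_sd, sign alternating across informative genes
    signs = np.where(np.arange(spec.n_informative) % 2 == 0, 1.0, -1.0)
    values[: spec.n_informative, :n1] += (
        signs[:, None] * spec.effect_size * spec.noise_sd
    )
    if spec.raw_scale:
        values = np.exp2(values)
    labels = np.array([CLASS_NAMES[0]] * n1 + [CLASS_NAMES[1]] * n2)
    matrix = ExpressionMatrix(
        values=values,
        gene_ids=[_gene_id(i) for i in range(spec.n_genes)],
        sample_ids=[f"S{j:03d}" for j in range(n_samples)],
        labels=labels,
    )
    truth = {_gene_id(i) for i in range(spec.n_informative)}
    dataset = LabeledDataset(matrix=matrix, truth_informative=truth, spec=spec)
    if spec.has_contamination:
        dataset = inject_contamination(dataset, spec)
    return dataset


def inject_contamination(dataset: LabeledDataset, spec: SyntheticSpec) -> LabeledDataset:
    """Plant duplicate IDs, missing cells and flat rows into a clean dataset.

    Duplicated IDs are appended as noisy copies of existing rows (so the
    pre-collapse gene count is ``n_genes + n_replicate_ids``); flat rows
    replace non-informative rows in place; missing cells are MCAR at rate
    ``frac_missing``. The ground-truth set is unchanged.
    """
    spec.validate()
    m = dataset.matrix
    if len(set(m.gene_ids)) != len(m.gene_ids) or m.missing_mask.any():
        raise ValueError("inject_contamination expects a clean (uncontaminated) dataset")
    rng = np.random.default_rng(spec.seed + 1)
    values = m.values.copy()
    gene_ids = list(m.gene_ids)
    n_genes, n_samples = values.shape

    # flat rows: overwrite non-informative, non-duplicated rows with a
    # near-constant value (tiny jitter keeps them non-degenerate but far
    # below any sensible dispersion threshold)
    informative_rows = {i for i, g in enumerate(gene_ids) if g in dataset.truth_informative}
    candidates = [i for i in range(n_genes) if i not in informative_rows]
    if spec.n_flat_genes > len(candidates):
        raise ValueError("not enough non-informative rows for the requested flat genes")
    flat_rows = list(rng.choice(len(candidates), size=spec.n_flat_genes, replace=False))
    flat_rows = [candidates[i] for i in flat_rows]
    for r in flat_rows:
        level = float(values[r].mean())
        values[r] = level + rng.normal(0.0, 1e-9, size=n_samples)

    # duplicate IDs: append a noisy copy of chosen non-flat rows
    dup_candidates = [i for i in candidates if i not in set(flat_rows)]
    if spec.n_replicate_ids > len(dup_candidates):
        raise ValueError("not enough rows available to duplicate")
    dup_rows = list(rng.choice(len(dup_candidates), size=spec.n_replicate_ids, replace=False))
    dup_rows = [dup_candidates[i] for i in dup_rows]
    extra = values[dup_rows] + rng.normal(0.0, 0.05 * spec.noise_sd, size=(len(dup_rows), n_samples))
    values = np.vstack([values, extra]) if len(dup_rows) else values
    gene_ids = gene_ids + [gene_ids[i] for i in dup_rows]

    # MCAR missing cells
    total = values.shape[0] * values.shape[1]
    mask = np.zeros(values.shape, dtype=bool)
    if spec.frac_missing > 0:
        n_missing = int(round(spec.frac_missing * total))
        flat_idx = rng.choice(total, size=n_missing, replace=False)
        mask.flat[flat_idx] = True
        if mask.all(axis=1).any() or mask.all(axis=0).any():
            raise ValueError(
                "frac_missing would erase an entire gene row or sample column"
            )
    values = values.copy()
    values[mask] = np.nan

    matrix = ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        sample_ids=list(m.sample_ids),
        labels=m.labels.copy(),
        missing_mask=mask,
    )
    return LabeledDataset(matrix=matrix, truth_informative=set(dataset.truth_informative), spec=spec)


def write_truth(truth: set[str], path: str | Path) -> None:
    """One gene ID per line, sorted."""
    Path(path).write_text("".join(f"{g}\n" for g in sorted(truth)))


def read_truth(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}
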