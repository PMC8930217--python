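"""Generate a two-class expression matrix with planted differential genes.

The generator draws gene baselines, shifts a chosen set of informative
genes between the classes by a fixed number of noise SDs, and (optionally)
plants the defects real microarray tables carry: duplicated gene IDs,
missing cells and near-constant rows.
"""
import numpy as np

import weedfs as w

spec = w.SyntheticSpec(
    n_genes=500,
    n_informative=20,
    n_samples_per_class=(52, 50),
    effect_size=2.0,
    raw_scale=True,       # skewed positive intensities, as scanners report
    frac_missing=0.01,
    n_replicate_ids=5,
    n_flat_genes=3,
    seed=7,
)
ds = w.generate_dataset(spec)
m = ds.matrix

print(f"matrix: {m.n_genes} genes x {m.n_samples} samples")
print(f"labels: {(m.labels == 'tumor').sum()} tumor, {(m.labels == 'normal').sum()} normal")
print(f"missing cells: {m.missing_mask.sum()} ({100 * m.missing_mask.mean():.2f}%)")
ids, counts = np.unique(m.gene_ids, return_counts=True)
print(f"duplicated gene IDs: {(counts >= 2).sum()}")
print(f"ground-truth informative genes: {len(ds.truth_informative)} (IDs known for scoring)")
# The matrix has 505 rows (500 genes + 5 noisy replicate rows); the truth
# set lets downstream selection be scored against what was actually planted.
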