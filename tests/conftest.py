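import numpy as np
import pytest

import weedfs as w


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, handmade, with one missing cell."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [8.0, 4.0, 2.0, 1.0],
            [5.0, np.nan, 5.0, 5.0],
        ]
    )
    return w.ExpressionMatrix(
        values=values,
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        labels=np.array(["tumor", "tumor", "normal", "normal"]),
    )


@pytest.fixture(scope="session")
def clean_dataset():
    """200-gene two-class dataset with 10 planted genes, no contamination."""
    spec = w.SyntheticSpec(
        n_genes=200,
        n_informative=10,
        n_samples_per_class=(60, 60),
        effect_size=2.0,
        noise_sd=1.0,
        seed=1,
    )
    return w.generate_dataset(spec)


@pytest.fixture(scope="session")
def contaminated_dataset():
    """Raw-scale dataset with duplicate IDs, missing cells and flat rows."""
    spec = w.SyntheticSpec(
        n_genes=200,
        n_informative=10,
        n_samples_per_class=(60, 60),
        effect_size=2.0,
        noise_sd=1.0,
        frac_missing=0.01,
        n_replicate_ids=5,
        n_flat_genes=3,
        raw_scale=True,
        seed=1,
    )
    return w.generate_dataset(spec)


@pytest.fixture(scope="session")
def strong_signal_8gene():
    """8 genes, 2 planted at strong effect: small enough for brute force."""
    spec = w.SyntheticSpec(
        n_genes=8,
        n_informative=2,
        n_samples_per_class=(30, 30),
        effect_size=2.0,
        seed=42,
    )
    ds = w.generate_dataset(spec)
    matrix = w.run_preprocess(ds.matrix, w.PreprocessConfig(do_log=False)).matrix
    return ds, matrix
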