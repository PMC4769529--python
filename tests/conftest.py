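import numpy as np
import pytest

from tagarray.panel_io import HaplotypePanel, Variant


def build_panel(columns, positions=None, statuses=None, populations=None,
                chrom="1", ids=None):
    """Panel from an explicit haplotype matrix given column-wise.

    ``columns``: list of per-variant allele tuples (one entry per
    haplotype row; length must be even).
    """
    H = np.array(columns, dtype=np.int8).T
    n_hap, n_var = H.shape
    assert n_hap % 2 == 0
    positions = positions or [100 * (j + 1) for j in range(n_var)]
    statuses = statuses or ["validated"] * n_var
    ids = ids or [f"v{j}" for j in range(n_var)]
    variants = [
        Variant(id=ids[j], chrom=chrom, pos=positions[j], ref_allele="A",
                alt_allele="G", validation_status=statuses[j])
        for j in range(n_var)
    ]
    sample_ids = [f"s{i}" for i in range(n_hap // 2)]
    return HaplotypePanel(
        variants=variants,
        haplotypes=H,
        sample_ids=sample_ids,
        populations=populations or {},
    )


def random_panel(rng, n_samples=10, n_variants=8, positions=None, statuses=None):
    """Random polymorphic-ish panel for property tests."""
    while True:
        H = (rng.random((2 * n_samples, n_variants)) < rng.uniform(
            0.2, 0.8, size=n_variants)).astype(np.int8)
        # ensure every column is polymorphic
        mono = (H.sum(axis=0) == 0) | (H.sum(axis=0) == 2 * n_samples)
        if not mono.any():
            break
    cols = [tuple(H[:, j]) for j in range(n_variants)]
    return build_panel(cols, positions=positions, statuses=statuses)


@pytest.fixture
def rng():
    return np.random.default_rng(20160227)
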