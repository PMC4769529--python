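"""Allele frequencies and pairwise linkage-disequilibrium r² on phased
haplotypes.

r² is computed directly from phased haplotype counts:
``r² = D² / (p_a (1-p_a) p_b (1-p_b))`` with ``D = P(ab) - p_a p_b``,
which equals the squared Pearson correlation of the two 0/1 allele
columns.  LD involving a monomorphic variant is *undefined*, signalled by
:class:`MonomorphicVariantError` (scalar API) or NaN (matrix API), never
silently reported as zero.
"""

from __future__ import annotations

import numpy as np

from .panel_io import HaplotypePanel


class MonomorphicVariantError(ValueError):
    """LD requested for a variant with no variation in scope."""


def _haplotype_block(panel: HaplotypePanel, population: str | None) -> np.ndarray:
    samples = panel.samples_in_population(population)
    if not samples:
        raise ValueError(f"no samples in population {population!r}")
    return panel.haplotypes[panel.haplotype_rows(samples)]


def allele_frequency(
    panel: HaplotypePanel, variant: str, population: str | None = None
) -> float:
    """Alternate-allele frequency over the selected haplotypes."""
    H = _haplotype_block(panel, population)
    return float(H[:, panel.variant_index(variant)].mean())


def minor_allele_frequency(
    panel: HaplotypePanel, variant: str, population: str | None = None
) -> float:
    """min(p, 1-p) of the alternate-allele frequency; in [0, 0.5]."""
    p = allele_frequency(panel, variant, population)
    return min(p, 1.0 - p)


def minor_allele_frequencies(
    panel: HaplotypePanel, population: str | None = None
) -> np.ndarray:
    """Vector of MAFs for every panel variant (panel order)."""
    H = _haplotype_block(panel, population)
    p = H.mean(axis=0)
    return np.minimum(p, 1.0 - p)


def pairwise_r2(
    panel: HaplotypePanel, a: str, b: str, population: str | None = None
) -> float:
    """LD r² between two variants from phased haplotype counts.

    Raises
    ------
    MonomorphicVariantError
        If either variant is monomorphic in the selected haplotypes; LD is
        undefined there, which is distinct from r² = 0.
    """
    H = _haplotype_block(panel, population)
    xa = H[:, panel.variant_index(a)].astype(float)
    xb = H[:, panel.variant_index(b)].astype(float)
    pa, pb = xa.mean(), xb.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va == 0.0:
        raise MonomorphicVariantError(f"variant {a!r} is monomorphic in scope")
    if vb == 0.0:
        raise MonomorphicVariantError(f"variant {b!r} is monomorphic in scope")
    d = (xa * xb).mean() - pa * pb
    return min(1.0, d * d / (va * vb))


def r2_matrix(H: np.ndarray, cols_a: np.ndarray, cols_b: np.ndarray) -> np.ndarray:
    """r² between every column of ``H[:, cols_a]`` and ``H[:, cols_b]``.

    Vectorized over pairs; entries involving a monomorphic column are NaN.
    ``H`` is a haplotype block (rows = haplotypes, entries 0/1).
    """
    A = H[:, cols_a].astype(np.float64)
    B = H[:, cols_b].astype(np.float64)
    n = A.shape[0]
    pa = A.mean(axis=0)
    pb = B.mean(axis=0)
    va = pa * (1 - pa)
    vb = pb * (1 - pb)
    joint = (A.T @ B) / n  # P(ab)
    d = joint - np.outer(pa, pb)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = d * d / np.outer(va, vb)
    r2[va == 0, :] = np.nan
    r2[:, vb == 0] = np.nan
    return np.minimum(r2, 1.0, out=r2, where=~np.isnan(r2))


def r2_table(
    panel: HaplotypePanel,
    ids_a,
    ids_b,
    population: str | None = None,
) -> np.ndarray:
    """r² matrix between two sets of panel variants (NaN where undefined)."""
    H = _haplotype_block(panel, population)
    ia = np.asarray([panel.variant_index(v) for v in ids_a], dtype=np.intp)
    ib = np.asarray([panel.variant_index(v) for v in ids_b], dtype=np.intp)
    return r2_matrix(H, ia, ib)
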