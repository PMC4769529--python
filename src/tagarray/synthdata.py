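"""Synthetic data: founder-mosaic haplotype panels and pilot QC fixtures.

The simulator is a founder-mosaic model rather than a full coalescent:
founder haplotypes are drawn site-wise from a chosen founder MAF law, and
every descendant haplotype is a recombinant mosaic of founders (switching
founders between adjacent sites with a fixed probability) with per-site
copy errors.  This produces the block-LD structure with distance-decaying
r² that the tagging and imputation protocols need, is fully seeded, and
runs at desk scale.  Population structure, when requested, is modelled as
per-population drift of founder allele frequencies — enough to produce
population-dependent coverage differences.

The pilot QC fixture reproduces a published genotyping pilot's printed
sample and marker counts exactly (646,247 markers across seven
classification labels and three validation statuses; 636 study samples
with one scan failure, eight DQC failures and five call-rate failures,
plus seven negative controls) so the QC decision rules can be checked
against known totals without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import GenotypeMatrix, HaplotypePanel, Variant


@dataclass(frozen=True)
class SimParams:
    """Founder-mosaic simulation parameters.

    n_founders
        Number of founder haplotypes; fewer founders means longer shared
        haplotypes and stronger LD.
    n_haplotypes
        Total descendant haplotypes (must be even; two per sample).
    n_sites
        Biallelic sites, placed uniformly over ``region_length_bp``.
    recomb_prob_per_site
        Probability of switching founders between adjacent sites.
    mutation_prob_per_site
        Per-site allele flip probability on descendants.
    founder_maf_law
        "uniform" (MAF ~ U[0.05, 0.5]) or "beta" (frequency ~ Beta(0.5,
        0.5), a U-shaped spectrum with common and rare sites).
    validated_fraction
        Fraction of sites marked manufacturer-validated.
    """

    n_founders: int = 20
    n_haplotypes: int = 200
    n_sites: int = 200
    region_length_bp: int = 1_000_000
    recomb_prob_per_site: float = 0.01
    mutation_prob_per_site: float = 0.001
    founder_maf_law: str = "uniform"
    validated_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_founders > self.n_haplotypes:
            raise ValueError("n_founders must be <= n_haplotypes")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (two per sample)")
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        for name in ("recomb_prob_per_site", "mutation_prob_per_site"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.founder_maf_law not in ("uniform", "beta"):
            raise ValueError(f"unknown founder_maf_law {self.founder_maf_law!r}")


def _founder_frequencies(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    if params.founder_maf_law == "uniform":
        maf = rng.uniform(0.05, 0.5, size=params.n_sites)
        flip = rng.random(params.n_sites) < 0.5
        return np.where(flip, 1.0 - maf, maf)
    return rng.beta(0.5, 0.5, size=params.n_sites)


def simulate_panel(
    params: SimParams,
    populations: list[tuple[str, int, float]] | None = None,
) -> HaplotypePanel:
    """Simulate a phased panel under the founder-mosaic model.

    Parameters
    ----------
    populations
        Optional list of (name, n_samples, drift_sd); each population
        gets its own founder set drawn from drift-perturbed frequencies
        (clipped to [0.02, 0.98]).  When omitted, all samples form one
        unlabeled population using ``n_haplotypes``.

    The same seed always yields an identical panel.
    """
    rng = np.random.default_rng(params.seed)
    base_freq = _founder_frequencies(params, rng)
    positions = np.sort(
        rng.choice(
            np.arange(1, params.region_length_bp + 1),
            size=params.n_sites,
            replace=False,
        )
    )
    validated = rng.random(params.n_sites) < params.validated_fraction

    if populations is None:
        populations = [("", params.n_haplotypes // 2, 0.0)]

    blocks = []
    sample_ids: list[str] = []
    pop_of: dict[str, str] = {}
    for pop_name, n_samples, drift in populations:
        freq = np.clip(
            base_freq + rng.normal(0.0, drift, size=params.n_sites), 0.02, 0.98
        )
        founders = (
            rng.random((params.n_founders, params.n_sites)) < freq
        ).astype(np.int8)
        n_hap = 2 * n_samples
        # mosaic copying paths: founder index per (haplotype, site)
        start = rng.integers(0, params.n_founders, size=n_hap)
        switches = rng.random((n_hap, params.n_sites - 1)) < params.recomb_prob_per_site
        new_founder = rng.integers(0, params.n_founders, size=(n_hap, params.n_sites - 1))
        path = np.empty((n_hap, params.n_sites), dtype=np.intp)
        path[:, 0] = start
        for j in range(1, params.n_sites):
            stay = ~switches[:, j - 1]
            path[:, j] = np.where(stay, path[:, j - 1], new_founder[:, j - 1])
        haps = founders[path, np.arange(params.n_sites)[None, :]]
        flips = rng.random(haps.shape) < params.mutation_prob_per_site
        haps = np.where(flips, 1 - haps, haps).astype(np.int8)
        blocks.append(haps)
        prefix = f"{pop_name}_" if pop_name else "S"
        ids = [f"{prefix}{i:04d}" for i in range(n_samples)]
        sample_ids.extend(ids)
        if pop_name:
            pop_of.update({s: pop_name for s in ids})

    variants = [
        Variant(
            id=f"var{j:05d}",
            chrom="1",
            pos=int(positions[j]),
            ref_allele="A",
            alt_allele="G",
            validation_status="validated" if validated[j] else "de_novo",
        )
        for j in range(params.n_sites)
    ]
    return HaplotypePanel(
        variants=variants,
        haplotypes=np.vstack(blocks),
        sample_ids=sample_ids,
        populations=pop_of,
    )


# ---------------------------------------------------------------------------
# Pilot QC fixture


# (classification, validated, failed_validation, de_novo) marker counts of
# the pilot genotyping fixture; column/row totals are 525513 / 48923 /
# 71811 and 646247 overall.
PILOT_MARKER_COUNTS = (
    ("PolyHighResolution", 441120, 17595, 7547),
    ("NoMinorHom", 62639, 6360, 6173),
    ("MonoHighResolution", 12095, 7061, 28614),
    ("Other", 6031, 14515, 27537),
    ("CallRateBelowThreshold", 3078, 2856, 1080),
    ("OTV", 370, 535, 860),
    ("Hemizygous", 180, 1, 0),
)

PILOT_N_STUDY_SAMPLES = 636
PILOT_N_SCAN_FAIL = 1
PILOT_N_DQC_FAIL = 8
PILOT_N_CALLRATE_FAIL = 5
PILOT_N_NEGATIVE_CONTROLS = 7

# nominal call rates per classification, used only to fill the manifest's
# call_rate column with plausible values consistent with each label
_CLASS_CALL_RATE = {
    "PolyHighResolution": 0.998,
    "NoMinorHom": 0.997,
    "MonoHighResolution": 0.996,
    "Other": 0.90,
    "CallRateBelowThreshold": 0.80,
    "OTV": 0.95,
    "Hemizygous": 0.96,
}


def make_pilot_qc_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample and marker QC tables reproducing the pilot's printed counts.

    Returns (samples, markers): 636 study samples (1 scan failure, 8 with
    DQC below 0.82, 5 with stage-1 call rate below 0.97, the rest clean)
    plus 7 negative controls, and 646,247 best-probeset marker records
    with the exact per-(classification x validation status) counts of the
    pilot.  Deterministic — no randomness involved.
    """
    n = PILOT_N_STUDY_SAMPLES
    sample_ids = [f"SAMP{i:04d}" for i in range(1, n + 1)]
    plates = [f"P{(i // 96) + 1:02d}" for i in range(n)]
    scan_ok = [True] * n
    dqc: list[float | None] = [0.95] * n
    cr: list[float | None] = [0.995] * n
    k = 0
    for _ in range(PILOT_N_SCAN_FAIL):
        scan_ok[k] = False
        dqc[k] = None
        cr[k] = None
        k += 1
    for i in range(PILOT_N_DQC_FAIL):
        dqc[k] = 0.70 + 0.01 * i  # all < 0.82
        cr[k] = None
        k += 1
    for i in range(PILOT_N_CALLRATE_FAIL):
        cr[k] = 0.90 + 0.01 * i  # all < 0.97
        k += 1
    n_neg = PILOT_N_NEGATIVE_CONTROLS
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids + [f"NEG{i:02d}" for i in range(1, n_neg + 1)],
            "plate_id": plates + [f"P{i:02d}" for i in range(1, n_neg + 1)],
            "control_type": ["study"] * n + ["negative_control"] * n_neg,
            "scan_ok": scan_ok + [True] * n_neg,
            "dqc": [np.nan if v is None else v for v in dqc] + [0.30] * n_neg,
            "stage1_call_rate": [np.nan if v is None else v for v in cr]
            + [np.nan] * n_neg,
        }
    )

    statuses = ("validated", "failed_validation", "de_novo")
    classification = []
    validation = []
    for cls, *counts in PILOT_MARKER_COUNTS:
        for status, count in zip(statuses, counts):
            classification.extend([cls] * count)
            validation.extend([status] * count)
    total = len(classification)
    markers = pd.DataFrame(
        {
            "marker_id": [f"MK{i:07d}" for i in range(1, total + 1)],
            "probeset_id": [f"PS{i:07d}-A" for i in range(1, total + 1)],
            "classification": pd.array(classification),
            "validation_status": pd.array(validation),
            "call_rate": [ _CLASS_CALL_RATE[c] for c in classification ],
        }
    )
    return samples, markers


def corrupt_calls(
    calls: GenotypeMatrix,
    discordance_rate: float,
    missing_rate: float,
    seed: int = 0,
) -> GenotypeMatrix:
    """Seeded random corruption of a genotype matrix.

    Each non-missing call is replaced by one of the two other genotype
    values with probability ``discordance_rate``, and independently set
    missing with probability ``missing_rate``.  Rates of 0 return an
    identical matrix; the same seed always yields the same corruption.
    """
    for name, rate in (("discordance_rate", discordance_rate), ("missing_rate", missing_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = calls.calls.copy()
    called = out >= 0
    flip = called & (rng.random(out.shape) < discordance_rate)
    if flip.any():
        # shift by 1 or 2 mod 3 -> a uniformly chosen *different* genotype
        shift = rng.integers(1, 3, size=int(flip.sum()))
        out[flip] = (out[flip] + shift) % 3
    drop = called & (rng.random(out.shape) < missing_rate)
    out[drop] = -1
    return GenotypeMatrix(
        marker_ids=list(calls.marker_ids),
        sample_ids=list(calls.sample_ids),
        calls=out,
    )
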