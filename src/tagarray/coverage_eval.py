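"""Hold-out imputation coverage protocol.

The evaluation mimics how array coverage is measured against a sequenced
reference cohort: samples of one population are partitioned into small
hold-out groups (default size 10); each group is restricted to the array
sites, imputed against the panel with that group (and any related
samples) removed, and the imputed dosages are pooled across groups.  Per
variant, obsRSQ is the squared Pearson correlation between pooled imputed
dosage and the measured genotype; coverage at a threshold t is the
fraction of defined-obsRSQ variants with obsRSQ >= t, summarized per MAF
stratum and region class.

obsRSQ is undefined when the measured genotype does not vary among the
evaluated samples; undefined variants are excluded from both numerator
and denominator and reported separately.  When the measured genotype
varies but the imputed dosage is constant, the dosage carries no
information and obsRSQ is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .impute_engine import HMMParams, impute_dosages
from .ld_core import minor_allele_frequencies
from .panel_io import HaplotypePanel, Region

log = logging.getLogger(__name__)


@dataclass
class HoldoutPlan:
    """Disjoint hold-out groups of sample ids for one population."""

    groups: list[list[str]]
    group_size: int
    excluded_samples: set[str] = field(default_factory=set)
    seed: int = 0
    population: str | None = None

    def __post_init__(self):
        seen: set[str] = set()
        for g in self.groups:
            for s in g:
                if s in seen:
                    raise ValueError(f"sample {s!r} appears in two groups")
                if s in self.excluded_samples:
                    raise ValueError(f"excluded sample {s!r} appears in a group")
                seen.add(s)

    @property
    def all_samples(self) -> list[str]:
        return [s for g in self.groups for s in g]


def make_holdout_groups(
    panel: HaplotypePanel,
    population: str | None,
    group_size: int = 10,
    exclusions=(),
    seed: int = 0,
) -> HoldoutPlan:
    """Seeded random partition of eligible samples into hold-out groups.

    Samples with known or cryptic relatedness are supplied via
    ``exclusions`` and appear in no group (nor, later, in any reference
    set).  A final remainder group smaller than ``group_size`` is kept.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    exclusions = set(exclusions)
    eligible = [
        s for s in panel.samples_in_population(population) if s not in exclusions
    ]
    if len(eligible) < group_size:
        raise ValueError(
            f"population {population!r} has {len(eligible)} eligible samples; "
            f"need at least one full group of {group_size}"
        )
    rng = np.random.default_rng(seed)
    order = [eligible[i] for i in rng.permutation(len(eligible))]
    groups = [order[i : i + group_size] for i in range(0, len(order), group_size)]
    return HoldoutPlan(
        groups=groups,
        group_size=group_size,
        excluded_samples=exclusions,
        seed=seed,
        population=population,
    )


def evaluate_imputation_coverage(
    panel: HaplotypePanel,
    array_sites,
    plan: HoldoutPlan,
    params: HMMParams | None = None,
) -> pd.DataFrame:
    """Run the hold-out protocol and tabulate per-variant obsRSQ.

    For each group, the group's samples are restricted to the array
    sites and imputed against the panel minus the group and minus the
    plan's exclusions; dosages are pooled across groups.  Returns a
    DataFrame with one row per panel variant: variant_id, chrom, pos,
    population, maf (population MAF in the full panel), typed, obsrsq
    (NaN when undefined) and n_samples_evaluated.
    """
    params = params or HMMParams()
    array_sites = list(dict.fromkeys(array_sites))
    missing = set(array_sites) - set(panel.variant_ids)
    if missing:
        raise ValueError(f"array sites absent from panel: {sorted(missing)[:3]}")

    pooled_samples: list[str] = []
    pooled_dosages: list[np.ndarray] = []
    for group in plan.groups:
        overlap = set(group) & plan.excluded_samples
        if overlap:
            raise ValueError(f"group contains excluded samples: {sorted(overlap)}")
        reference = panel.drop_samples(set(group) | plan.excluded_samples)
        held_out = panel.subset_samples(group).subset_variants(array_sites)
        dm = impute_dosages(reference, held_out, array_sites, params)
        # dm variant order is the reference (= panel) order
        pooled_samples.extend(dm.sample_ids)
        pooled_dosages.append(dm.dosages)
    dosages = np.vstack(pooled_dosages)  # (n_eval, n_variants) in panel order

    measured = panel.genotypes(pooled_samples).astype(float)
    obsrsq = _columnwise_squared_correlation(dosages, measured)

    mafs = minor_allele_frequencies(panel, plan.population)
    typed = np.isin(np.asarray(panel.variant_ids), np.asarray(array_sites))
    return pd.DataFrame(
        {
            "variant_id": panel.variant_ids,
            "chrom": [v.chrom for v in panel.variants],
            "pos": [v.pos for v in panel.variants],
            "population": plan.population or "all",
            "maf": mafs,
            "typed": typed,
            "obsrsq": obsrsq,
            "n_samples_evaluated": len(pooled_samples),
        }
    )


def _columnwise_squared_correlation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation per column; NaN when y is constant,
    0 when y varies but x is constant."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    vx = (xc * xc).sum(axis=0)
    vy = (yc * yc).sum(axis=0)
    cov = (xc * yc).sum(axis=0)
    out = np.full(x.shape[1], np.nan)
    defined = vy > 0
    informative = defined & (vx > 0)
    out[defined & ~informative] = 0.0
    out[informative] = (cov[informative] ** 2) / (
        vx[informative] * vy[informative]
    )
    return np.clip(out, 0.0, 1.0)  # NaN (undefined) propagates through clip


GENOME_WIDE = "genome_wide"


def summarize_coverage(
    table: pd.DataFrame,
    maf_strata=(0.01, 0.05),
    thresholds=(0.8,),
    regions: list[Region] | None = None,
    squared: bool = True,
) -> pd.DataFrame:
    """Stratified coverage summary of an obsRSQ table.

    One output row per (population, region class, MAF stratum): the
    fraction of defined-obsRSQ variants meeting each threshold
    (``coverage_at_<t>`` columns, using >=), the mean obsRSQ over defined
    values, and defined/undefined counts.  Region classes come from the
    supplied (flanked) regions plus a genome-wide class covering all
    variants.  An empty stratum yields NaN coverage, never 0.

    ``squared=False`` reports the unsquared (signed-magnitude) statistic
    sqrt(obsRSQ) instead; thresholds then apply to |r|.
    """
    if table.empty:
        raise ValueError("obsRSQ table is empty")
    region_classes: dict[str, pd.Series] = {
        GENOME_WIDE: pd.Series(True, index=table.index)
    }
    for r in regions or []:
        chrom_match = table["chrom"].map(
            lambda c, r=r: _norm(c) == _norm(r.chrom)
        )
        inside = (
            chrom_match
            & (table["pos"] - 1 >= r.effective_start)
            & (table["pos"] - 1 < r.effective_end)
        )
        region_classes[r.name] = inside

    rows = []
    stat = table["obsrsq"] if squared else np.sqrt(table["obsrsq"])
    for pop, pop_mask in table.groupby("population").groups.items():
        pmask = pd.Series(False, index=table.index)
        pmask.loc[pop_mask] = True
        for region_name, rmask in region_classes.items():
            for maf_min in maf_strata:
                mask = pmask & rmask & (table["maf"] >= maf_min)
                vals = stat[mask]
                defined = vals.dropna()
                row = {
                    "population": pop,
                    "region": region_name,
                    "maf_min": maf_min,
                    "n_variants": int(len(defined)),
                    "n_undefined": int(vals.isna().sum()),
                    "mean_obsrsq": (
                        float(defined.mean()) if len(defined) else np.nan
                    ),
                }
                for t in thresholds:
                    row[f"coverage_at_{t:g}"] = (
                        float((defined >= t).mean()) if len(defined) else np.nan
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def threshold_sweep(
    table: pd.DataFrame,
    thresholds,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Coverage as a function of obsRSQ threshold (one row per threshold).

    Coverage is non-increasing in the threshold by construction.
    """
    mask = table["maf"] >= maf_min
    defined = table.loc[mask, "obsrsq"].dropna()
    rows = [
        {
            "threshold": float(t),
            "coverage": float((defined >= t).mean()) if len(defined) else np.nan,
        }
        for t in thresholds
    ]
    return pd.DataFrame(rows)


def _norm(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom
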