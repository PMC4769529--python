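"""Sample- and marker-level genotyping QC decision pipeline.

Sample QC applies, in order: scan failure, dish QC (DQC) below threshold
(default 0.82, strict <), then stage-1 call rate below threshold (default
0.97, strict <).  Each sample gets at most one primary failure reason, so
the reported failure counts are disjoint, matching sequential exclusion.
Negative controls are segregated and never enter pass-rate denominators.

Marker QC consumes probeset classifications (cluster-quality labels
produced upstream from intensity data) and the marker's manufacturer
validation status.  After best-probeset selection, markers classified
PolyHighResolution or NoMinorHom are kept; MonoHighResolution is kept
only when previously validated or de novo; Other, CallRateBelowThreshold,
OTV and Hemizygous are removed by default (conditional keeps for OTV and
Hemizygous are available behind flags).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import GenotypeMatrix, validate_marker_manifest

log = logging.getLogger(__name__)

# failure reason codes
SCAN_FAIL = "SCAN_FAIL"
DQC_BELOW_MIN = "DQC_BELOW_MIN"
STAGE1_CALLRATE_BELOW_MIN = "STAGE1_CALLRATE_BELOW_MIN"
CLASS_OTHER = "CLASS_OTHER"
CLASS_CALLRATE = "CLASS_CALLRATE"
CLASS_OTV = "CLASS_OTV"
CLASS_HEMIZYGOUS = "CLASS_HEMIZYGOUS"
CLASS_MONO_FAILED_VALIDATION = "CLASS_MONO_FAILED_VALIDATION"

# best-probeset preference, best first
CLASSIFICATION_RANK = (
    "PolyHighResolution",
    "NoMinorHom",
    "MonoHighResolution",
    "Hemizygous",
    "OTV",
    "CallRateBelowThreshold",
    "Other",
)


@dataclass(frozen=True, slots=True)
class QCThresholds:
    dqc_min: float = 0.82
    stage1_call_rate_min: float = 0.97
    hapmap_marker_call_rate_min: float = 0.95

    def __post_init__(self):
        for name in ("dqc_min", "stage1_call_rate_min", "hapmap_marker_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def qc_samples(
    records: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply the sample QC decision rules.

    ``records`` needs columns sample_id, plate_id, control_type, scan_ok,
    dqc, stage1_call_rate.  Returns (decisions, plate_summary, summary):

    - decisions: one row per non-negative-control sample with ``passed``
      and ``reason_codes`` (list; empty iff passed);
    - plate_summary: per-plate pass rate and mean stage-1 call rate over
      samples passing the DQC rule;
    - summary: counts (n_samples, n_passed, pass_rate, per-reason counts,
      n_negative_controls).
    """
    if records.empty:
        raise ValueError("no sample records")
    if records["sample_id"].duplicated().any():
        dup = records.loc[records["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")

    neg = records[records["control_type"] == "negative_control"]
    study = records[records["control_type"] != "negative_control"]

    reasons = []
    for rec in study.itertuples(index=False):
        if not rec.scan_ok:
            reasons.append([SCAN_FAIL])
        elif pd.notna(rec.dqc) and rec.dqc < thresholds.dqc_min:
            reasons.append([DQC_BELOW_MIN])
        elif (
            pd.notna(rec.stage1_call_rate)
            and rec.stage1_call_rate < thresholds.stage1_call_rate_min
        ):
            reasons.append([STAGE1_CALLRATE_BELOW_MIN])
        else:
            reasons.append([])
    decisions = pd.DataFrame(
        {
            "sample_id": study["sample_id"].to_numpy(),
            "plate_id": study["plate_id"].to_numpy(),
            "passed": [not r for r in reasons],
            "reason_codes": reasons,
        }
    ).sort_values("sample_id", kind="stable", ignore_index=True)

    # plate summary: pass rate; mean stage-1 call rate over DQC-passing scans
    dqc_pass = (
        study["scan_ok"]
        & study["dqc"].notna()
        & (study["dqc"] >= thresholds.dqc_min)
    )
    plate_rows = []
    passed_by_sample = dict(zip(decisions["sample_id"], decisions["passed"]))
    for plate, grp in study.groupby("plate_id"):
        grp_pass = [passed_by_sample[s] for s in grp["sample_id"]]
        cr = grp.loc[dqc_pass.reindex(grp.index, fill_value=False), "stage1_call_rate"]
        plate_rows.append(
            {
                "plate_id": plate,
                "n_samples": len(grp),
                "pass_rate": float(np.mean(grp_pass)),
                "mean_stage1_call_rate": float(cr.mean()) if len(cr) else np.nan,
            }
        )
    plate_summary = pd.DataFrame(plate_rows).sort_values(
        "plate_id", ignore_index=True
    )

    flat = [r[0] for r in reasons if r]
    summary = {
        "n_samples": int(len(study)),
        "n_passed": int(decisions["passed"].sum()),
        "pass_rate": float(decisions["passed"].mean()),
        "n_scan_fail": flat.count(SCAN_FAIL),
        "n_dqc_fail": flat.count(DQC_BELOW_MIN),
        "n_call_rate_fail": flat.count(STAGE1_CALLRATE_BELOW_MIN),
        "n_negative_controls": int(len(neg)),
    }
    return decisions, plate_summary, summary


def stage1_call_rate(calls: GenotypeMatrix, probeset_subset) -> pd.Series:
    """Per-sample fraction of non-missing calls over a designated subset
    of high-confidence markers."""
    subset = list(dict.fromkeys(probeset_subset))
    if not subset:
        raise ValueError("probeset subset is empty")
    idx = [calls.marker_index(m) for m in subset]
    block = calls.calls[idx]  # (subset, samples)
    rate = (block >= 0).mean(axis=0)
    return pd.Series(rate, index=calls.sample_ids, name="stage1_call_rate")


def select_best_probeset(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one probeset per marker: best classification, then highest
    call rate, then lexicographically smallest probeset id."""
    df = validate_marker_manifest(records).copy()
    rank = {c: i for i, c in enumerate(CLASSIFICATION_RANK)}
    df["_rank"] = df["classification"].map(rank)
    df = df.sort_values(
        ["marker_id", "_rank", "call_rate", "probeset_id"],
        ascending=[True, True, False, True],
        na_position="last",
        kind="stable",
    )
    best = df.drop_duplicates("marker_id", keep="first").drop(columns="_rank")
    return best.reset_index(drop=True)


def filter_markers(
    records: pd.DataFrame,
    keep_otv: bool = False,
    keep_hemizygous: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Marker keep/drop decisions on best-probeset records.

    Keeps PolyHighResolution and NoMinorHom unconditionally and
    MonoHighResolution only when validated or de novo; removes Other,
    CallRateBelowThreshold and (unless the corresponding flag is set)
    OTV and Hemizygous.  Returns (decisions, counts) where counts has
    ``kept``, ``removed`` and one entry per removal reason code.
    """
    counts = {
        "total": int(len(records)),
        CLASS_OTHER: 0,
        CLASS_CALLRATE: 0,
        CLASS_OTV: 0,
        CLASS_HEMIZYGOUS: 0,
        CLASS_MONO_FAILED_VALIDATION: 0,
    }
    if records.empty:
        counts.update(kept=0, removed=0)
        empty = pd.DataFrame(
            columns=["marker_id", "classification", "passed", "reason_codes"]
        )
        return empty, counts

    cls = records["classification"].to_numpy()
    vs = records["validation_status"].to_numpy()
    reason = np.full(len(records), "", dtype=object)
    reason[cls == "Other"] = CLASS_OTHER
    reason[cls == "CallRateBelowThreshold"] = CLASS_CALLRATE
    if not keep_otv:
        reason[cls == "OTV"] = CLASS_OTV
    if not keep_hemizygous:
        reason[cls == "Hemizygous"] = CLASS_HEMIZYGOUS
    mono_failed = (cls == "MonoHighResolution") & (vs == "failed_validation")
    reason[mono_failed] = CLASS_MONO_FAILED_VALIDATION

    passed = reason == ""
    decisions = pd.DataFrame(
        {
            "marker_id": records["marker_id"].to_numpy(),
            "classification": cls,
            "passed": passed,
            "reason_codes": [[r] if r else [] for r in reason],
        }
    )
    for code in (
        CLASS_OTHER,
        CLASS_CALLRATE,
        CLASS_OTV,
        CLASS_HEMIZYGOUS,
        CLASS_MONO_FAILED_VALIDATION,
    ):
        counts[code] = int((reason == code).sum())
    counts["kept"] = int(passed.sum())
    counts["removed"] = int((~passed).sum())
    return decisions, counts


def replicate_reproducibility(
    calls: GenotypeMatrix, pairs
) -> tuple[float, pd.Series]:
    """Average genotype match rate across replicate sample pairs.

    Per pair, the match fraction is computed over markers where both
    members are called; pairs with no mutually called marker are
    undefined and excluded with a warning.  Returns (unweighted mean,
    per-pair series indexed 'a|b').
    """
    rates = {}
    for a, b in pairs:
        ca = calls.sample_column(a)
        cb = calls.sample_column(b)
        both = (ca >= 0) & (cb >= 0)
        if not both.any():
            log.warning("replicate pair (%s, %s) has no mutually called markers", a, b)
            continue
        rates[f"{a}|{b}"] = float((ca[both] == cb[both]).mean())
    if not rates:
        raise ValueError("no replicate pair with mutually called markers")
    series = pd.Series(rates, name="reproducibility")
    return float(series.mean()), series


def concordance(
    calls: GenotypeMatrix,
    reference: GenotypeMatrix,
    marker_subset=None,
    min_ref_call_rate: float | None = None,
    per_genotype: bool = False,
) -> tuple[float, pd.Series]:
    """Average genotype concordance against an external reference.

    Alleles must be pre-harmonized.  Markers can be restricted to a
    subset and/or to those with reference call rate >=
    ``min_ref_call_rate``.  By default the match fraction is computed
    per shared sample over mutually called markers and averaged
    unweighted across samples; ``per_genotype=True`` pools all genotype
    comparisons instead.
    """
    shared_samples = [s for s in calls.sample_ids if s in set(reference.sample_ids)]
    if not shared_samples:
        raise ValueError("no shared samples between call sets")
    shared_markers = [
        m for m in calls.marker_ids if m in set(reference.marker_ids)
    ]
    if marker_subset is not None:
        keep = set(marker_subset)
        shared_markers = [m for m in shared_markers if m in keep]
    if min_ref_call_rate is not None:
        ref_rate = (reference.calls >= 0).mean(axis=1)
        ok = {
            m
            for m in shared_markers
            if ref_rate[reference.marker_index(m)] >= min_ref_call_rate
        }
        shared_markers = [m for m in shared_markers if m in ok]
    if not shared_markers:
        raise ValueError("no shared markers after filtering")

    ci = [calls.marker_index(m) for m in shared_markers]
    ri = [reference.marker_index(m) for m in shared_markers]
    per_sample = {}
    n_match = n_comp = 0
    for s in shared_samples:
        a = calls.calls[ci, calls.sample_index(s)]
        b = reference.calls[ri, reference.sample_index(s)]
        both = (a >= 0) & (b >= 0)
        if not both.any():
            continue
        matches = int((a[both] == b[both]).sum())
        per_sample[s] = matches / int(both.sum())
        n_match += matches
        n_comp += int(both.sum())
    if not per_sample:
        raise ValueError("no sample with mutually called markers")
    series = pd.Series(per_sample, name="concordance")
    overall = n_match / n_comp if per_genotype else float(series.mean())
    return float(overall), series


MAF_BINS = ("monomorphic", "(0,0.01)", "[0.01,0.05)", "[0.05,0.5]")


def maf_spectrum(calls: GenotypeMatrix) -> dict[str, int]:
    """Marker counts per MAF bin from observed genotypes.

    MAF is computed from non-missing diploid calls; bins are
    monomorphic, (0, 0.01), [0.01, 0.05) and [0.05, 0.5].  Markers with
    no called genotypes count as monomorphic.  Bin counts sum to the
    marker count.
    """
    if calls.calls.size == 0:
        raise ValueError("empty genotype matrix")
    g = calls.calls.astype(float)
    g[g < 0] = np.nan
    n_called = np.sum(~np.isnan(g), axis=1)
    with np.errstate(invalid="ignore"):
        p = np.nansum(g, axis=1) / (2 * n_called)
    maf = np.minimum(p, 1 - p)
    maf[n_called == 0] = 0.0
    counts = {
        "monomorphic": int((maf == 0).sum()),
        "(0,0.01)": int(((maf > 0) & (maf < 0.01)).sum()),
        "[0.01,0.05)": int(((maf >= 0.01) & (maf < 0.05)).sum()),
        "[0.05,0.5]": int((maf >= 0.05).sum()),
    }
    assert sum(counts.values()) == len(calls.marker_ids)
    return counts


def dedup_replicates(call_rates: pd.Series, replicate_groups) -> set[str]:
    """Pick which member of each replicate group to keep: highest overall
    call rate, ties broken by smallest sample id.  Returns ids to drop."""
    drop: set[str] = set()
    for group in replicate_groups:
        ranked = sorted(group, key=lambda s: (-call_rates.get(s, 0.0), s))
        drop.update(ranked[1:])
    return drop
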