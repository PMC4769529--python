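"""Multi-round greedy tag-SNP selection and direct-coverage/density
reporting for an array design.

The selection protocol runs in prioritized rounds.  The default schedule
mirrors the three-round design used for dense gene-region tagging:

1. targets with MAF >= 0.05 tagged at r² >= 0.9, validated candidates only;
2. remaining targets tagged at r² >= 0.8, validated candidates only;
3. remaining targets tagged at r² >= 0.9, non-validated candidates allowed.

Within a round the selection is a greedy set cover: the eligible candidate
tagging the largest number of still-untagged targets is added repeatedly.
A candidate that is itself a target tags itself (r² = 1).  Markers
selected in earlier rounds keep tagging for free in later rounds before
any new marker is added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import ld_core
from .panel_io import HaplotypePanel, Region

log = logging.getLogger(__name__)

VALIDATED_ONLY = "validated_only"
NON_VALIDATED_ALLOWED = "non_validated_allowed"


class UndefinedFractionError(ValueError):
    """A coverage fraction was requested over an empty denominator."""


@dataclass(frozen=True, slots=True)
class RoundSpec:
    """One tagging round: threshold plus candidate pool restriction."""

    round_index: int
    r2_min: float
    candidate_pool: str = VALIDATED_ONLY

    def __post_init__(self):
        if not 0.0 < self.r2_min <= 1.0:
            raise ValueError("r2_min must be in (0, 1]")
        if self.candidate_pool not in (VALIDATED_ONLY, NON_VALIDATED_ALLOWED):
            raise ValueError(f"unknown candidate_pool {self.candidate_pool!r}")


DEFAULT_ROUNDS = (
    RoundSpec(1, 0.9, VALIDATED_ONLY),
    RoundSpec(2, 0.8, VALIDATED_ONLY),
    RoundSpec(3, 0.9, NON_VALIDATED_ALLOWED),
)


@dataclass(frozen=True, slots=True)
class TagAssignment:
    target: str
    tag: str
    r2: float
    round_index: int
    population: str | None = None


@dataclass
class DesignSelection:
    """Result of tag selection: chosen markers, assignments, leftovers."""

    selected_markers: set[str] = field(default_factory=set)
    assignments: list[TagAssignment] = field(default_factory=list)
    untagged: set[str] = field(default_factory=set)
    dropped_low_maf: set[str] = field(default_factory=set)

    @property
    def tagged(self) -> set[str]:
        return {a.target for a in self.assignments}

    def per_round_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for a in self.assignments:
            counts[a.round_index] = counts.get(a.round_index, 0) + 1
        return counts


def _round_pool_mask(statuses: list[str], pool: str) -> np.ndarray:
    if pool == VALIDATED_ONLY:
        return np.asarray([s == "validated" for s in statuses])
    return np.ones(len(statuses), dtype=bool)


def select_tags(
    panel: HaplotypePanel,
    targets,
    candidates,
    rounds=DEFAULT_ROUNDS,
    maf_min: float = 0.05,
    population: str | None = None,
    window_bp: int = 1_000_000,
) -> DesignSelection:
    """Greedy multi-round tag selection.

    Parameters
    ----------
    targets, candidates
        Variant ids.  Candidates carry their validation status on the
        panel's Variant records.  Targets below ``maf_min`` in the
        population are dropped (with a logged count) before tagging.
    window_bp
        Maximum tag-target distance; pairs farther apart are ineligible.

    Returns
    -------
    DesignSelection
        Every surviving target ends up in exactly one of
        assigned / untagged; each assignment records the round in which
        the target was first tagged.
    """
    targets = list(dict.fromkeys(targets))
    candidates = list(dict.fromkeys(candidates))
    sel = DesignSelection()
    if not targets:
        sel.untagged = set()
        return sel

    mafs = {
        t: ld_core.minor_allele_frequency(panel, t, population) for t in targets
    }
    kept = [t for t in targets if mafs[t] >= maf_min]
    sel.dropped_low_maf = {t for t in targets if mafs[t] < maf_min}
    if sel.dropped_low_maf:
        log.info(
            "dropped %d/%d targets below MAF %g",
            len(sel.dropped_low_maf),
            len(targets),
            maf_min,
        )
    if not kept:
        return sel
    targets = kept

    cand_pos = np.asarray([panel.variant(c).pos for c in candidates])
    targ_pos = np.asarray([panel.variant(t).pos for t in targets])
    cand_chrom = np.asarray([panel.variant(c).chrom for c in candidates])
    targ_chrom = np.asarray([panel.variant(t).chrom for t in targets])
    statuses = [panel.variant(c).validation_status for c in candidates]

    if candidates:
        r2 = ld_core.r2_table(panel, candidates, targets, population)
    else:
        r2 = np.zeros((0, len(targets)))
    in_window = (np.abs(cand_pos[:, None] - targ_pos[None, :]) <= window_bp) & (
        cand_chrom[:, None] == targ_chrom[None, :]
    )
    r2 = np.where(in_window, r2, np.nan)
    # self-tagging: a candidate that is a target tags itself at r2 = 1
    tpos = {t: j for j, t in enumerate(targets)}
    for i, c in enumerate(candidates):
        if c in tpos:
            r2[i, tpos[c]] = 1.0

    untagged = np.ones(len(targets), dtype=bool)
    selected_mask = np.zeros(len(candidates), dtype=bool)

    for spec in rounds:
        pool = _round_pool_mask(statuses, spec.candidate_pool)
        covers = np.nan_to_num(r2, nan=-1.0) >= spec.r2_min  # (cand, targ)

        # free coverage by markers already selected in earlier rounds
        if selected_mask.any():
            for j in np.nonzero(untagged)[0]:
                elig = np.nonzero(selected_mask & covers[:, j])[0]
                if elig.size:
                    best = elig[np.argmax(r2[elig, j])]
                    sel.assignments.append(
                        TagAssignment(
                            target=targets[j],
                            tag=candidates[best],
                            r2=float(r2[best, j]),
                            round_index=spec.round_index,
                            population=population,
                        )
                    )
                    untagged[j] = False

        # greedy set cover over the round's pool
        while untagged.any():
            gain = (covers[:, untagged] & pool[:, None]).sum(axis=1)
            gain[selected_mask] = 0
            best_gain = gain.max() if gain.size else 0
            if best_gain == 0:
                break
            tied = np.nonzero(gain == best_gain)[0]
            best = min(tied, key=lambda i: _tie_key(i, r2, covers, untagged, statuses, cand_pos, candidates))
            selected_mask[best] = True
            for j in np.nonzero(untagged & covers[best])[0]:
                sel.assignments.append(
                    TagAssignment(
                        target=targets[j],
                        tag=candidates[best],
                        r2=float(r2[best, j]),
                        round_index=spec.round_index,
                        population=population,
                    )
                )
                untagged[j] = False

    sel.selected_markers = {candidates[i] for i in np.nonzero(selected_mask)[0]}
    sel.untagged = {targets[j] for j in np.nonzero(untagged)[0]}
    return sel


def _tie_key(i, r2, covers, untagged, statuses, cand_pos, candidates):
    """Tie-break: validated first, higher mean r² to newly tagged targets,
    smaller genomic position, then id (deterministic designs)."""
    newly = covers[i] & untagged
    mean_r2 = float(np.nanmean(r2[i, newly])) if newly.any() else 0.0
    return (
        0 if statuses[i] == "validated" else 1,
        -mean_r2,
        int(cand_pos[i]),
        candidates[i],
    )


def select_tags_multi(
    panel: HaplotypePanel,
    targets,
    candidates,
    populations,
    rounds=DEFAULT_ROUNDS,
    maf_min: float = 0.05,
    window_bp: int = 1_000_000,
) -> tuple[set[str], dict[str, DesignSelection]]:
    """Per-population selection, unioned into one design.

    Returns the unioned marker set and the per-population selections
    (from which per-population coverage can be reported).
    """
    per_pop: dict[str, DesignSelection] = {}
    union: set[str] = set()
    for pop in populations:
        sel = select_tags(
            panel, targets, candidates, rounds, maf_min, pop, window_bp
        )
        per_pop[pop] = sel
        union |= sel.selected_markers
    return union, per_pop


def direct_coverage(
    panel: HaplotypePanel,
    array_markers,
    targets,
    r2_min: float = 0.8,
    population: str | None = None,
    window_bp: int = 1_000_000,
) -> float:
    """Fraction of targets with at least one array marker at r² >= r2_min.

    A target that is itself on the array covers itself.  Raises
    :class:`UndefinedFractionError` for an empty target set (a fraction
    with no denominator is not 0).
    """
    targets = list(dict.fromkeys(targets))
    if not targets:
        raise UndefinedFractionError("coverage of an empty target set is undefined")
    array_markers = list(dict.fromkeys(array_markers))
    array_set = set(array_markers)
    covered = np.asarray([t in array_set for t in targets])
    if array_markers and not covered.all():
        r2 = ld_core.r2_table(panel, array_markers, targets, population)
        cand_pos = np.asarray([panel.variant(c).pos for c in array_markers])
        targ_pos = np.asarray([panel.variant(t).pos for t in targets])
        cand_chrom = np.asarray([panel.variant(c).chrom for c in array_markers])
        targ_chrom = np.asarray([panel.variant(t).chrom for t in targets])
        in_window = (
            np.abs(cand_pos[:, None] - targ_pos[None, :]) <= window_bp
        ) & (cand_chrom[:, None] == targ_chrom[None, :])
        hit = (np.nan_to_num(r2, nan=-1.0) >= r2_min) & in_window
        covered |= hit.any(axis=0)
    return float(covered.mean())


def density_report(region: Region, n_markers: int) -> int:
    """Average marker spacing: round(effective length / n_markers) in bp."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    # round half up, deterministically (avoid banker's rounding)
    return int(np.floor(region.effective_length / n_markers + 0.5))
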