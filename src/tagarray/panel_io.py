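"""Data model and readers/writers for haplotype panels, regions, marker
manifests, genotype call tables and JSON reports.

The central container is :class:`HaplotypePanel`: phased 0/1 haplotypes
(two rows per sample) over an ordered list of biallelic variants, with an
optional population label per sample.  Coordinates follow the standards of
the formats they come from: VCF positions are 1-based inclusive, BED
intervals are 0-based half-open, and all internal interval tests use the
half-open convention.  Chromosome names are normalized by stripping a
leading ``chr`` prefix so panels and region files from different sources
can be matched.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

VALIDATION_STATUSES = ("validated", "failed_validation", "de_novo")

MARKER_CLASSIFICATIONS = (
    "PolyHighResolution",
    "NoMinorHom",
    "MonoHighResolution",
    "Other",
    "CallRateBelowThreshold",
    "OTV",
    "Hemizygous",
)

MANIFEST_COLUMNS = (
    "marker_id",
    "probeset_id",
    "classification",
    "validation_status",
    "call_rate",
)

SAMPLE_TABLE_COLUMNS = (
    "sample_id",
    "plate_id",
    "control_type",
    "scan_ok",
    "dqc",
    "stage1_call_rate",
)

CONTROL_TYPES = ("study", "positive_control", "negative_control")

MISSING_CALL = -1  # internal encoding; "NA" on disk


class PanelIOError(ValueError):
    """Malformed input file or inconsistent panel data."""


class UnphasedGenotypeError(PanelIOError):
    """An unphased genotype was found where phased haplotypes are required."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix so 'chr19' and '19' compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _chrom_sort_key(chrom: str):
    # numeric chromosomes before lexical ones, so 2 < 10 < X
    return (0, int(chrom)) if chrom.isdigit() else (1, 0, chrom)


@dataclass(frozen=True, slots=True)
class Variant:
    """A biallelic variant with a manufacturer validation status."""

    id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    validation_status: str = "validated"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"variant {self.id}: ref and alt alleles are equal")
        if self.validation_status not in VALIDATION_STATUSES:
            raise ValueError(
                f"variant {self.id}: unknown validation_status "
                f"{self.validation_status!r}"
            )

    @property
    def sort_key(self):
        return (*_chrom_sort_key(normalize_chrom(self.chrom)), self.pos, self.id)


@dataclass(frozen=True, slots=True)
class Region:
    """A genomic interval (0-based half-open) with an optional flank."""

    chrom: str
    start: int
    end: int
    name: str = ""
    flank_bp: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"region {self.name or self.chrom}: start {self.start} >= end {self.end}"
            )
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")

    @property
    def effective_start(self) -> int:
        return max(0, self.start - self.flank_bp)

    @property
    def effective_end(self) -> int:
        return self.end + self.flank_bp

    @property
    def effective_length(self) -> int:
        return self.effective_end - self.effective_start

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether a 1-based position falls in the flanked interval."""
        return (
            normalize_chrom(chrom) == normalize_chrom(self.chrom)
            and self.effective_start <= pos - 1 < self.effective_end
        )


@dataclass
class HaplotypePanel:
    """Phased haplotypes over sorted biallelic variants.

    ``haplotypes`` has shape (2 * n_samples, n_variants); rows ``2i`` and
    ``2i + 1`` are the two haplotypes of sample ``i``.  Variants are kept
    sorted by (chrom, pos, id); the constructor reorders columns if needed.
    """

    variants: list[Variant]
    haplotypes: np.ndarray
    sample_ids: list[str]
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise PanelIOError("haplotypes must be a 2-D matrix")
        n_rows, n_cols = self.haplotypes.shape
        if n_rows != 2 * len(self.sample_ids):
            raise PanelIOError(
                f"{n_rows} haplotype rows for {len(self.sample_ids)} samples"
            )
        if n_cols != len(self.variants):
            raise PanelIOError(
                f"{n_cols} haplotype columns for {len(self.variants)} variants"
            )
        if n_cols and not np.isin(self.haplotypes, (0, 1)).all():
            raise PanelIOError("haplotype entries must all be 0 or 1")
        order = sorted(range(n_cols), key=lambda i: self.variants[i].sort_key)
        if order != list(range(n_cols)):
            self.variants = [self.variants[i] for i in order]
            self.haplotypes = self.haplotypes[:, order]
        self._index = {v.id: i for i, v in enumerate(self.variants)}
        if len(self._index) != len(self.variants):
            raise PanelIOError("duplicate variant ids in panel")

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in panel") from None

    def variant(self, variant_id: str) -> Variant:
        return self.variants[self.variant_index(variant_id)]

    def population_of(self, sample_id: str) -> str:
        return self.populations.get(sample_id, "other")

    def samples_in_population(self, population: str | None) -> list[str]:
        if population is None:
            return list(self.sample_ids)
        return [s for s in self.sample_ids if self.population_of(s) == population]

    def haplotype_rows(self, sample_ids=None) -> np.ndarray:
        """Row indices of the haplotypes belonging to the given samples."""
        if sample_ids is None:
            return np.arange(2 * self.n_samples)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        rows = []
        for s in sample_ids:
            if s not in pos:
                raise KeyError(f"sample {s!r} not in panel")
            rows.extend((2 * pos[s], 2 * pos[s] + 1))
        return np.asarray(rows, dtype=np.intp)

    def genotypes(self, sample_ids=None) -> np.ndarray:
        """Diploid alternate-allele counts, shape (n_samples, n_variants)."""
        rows = self.haplotype_rows(sample_ids)
        h = self.haplotypes[rows]
        return h[0::2] + h[1::2]

    # -- subsetting -------------------------------------------------------

    def subset_variants(self, variant_ids) -> "HaplotypePanel":
        idx = [self.variant_index(v) for v in variant_ids]
        idx = sorted(set(idx))
        return HaplotypePanel(
            variants=[self.variants[i] for i in idx],
            haplotypes=self.haplotypes[:, idx],
            sample_ids=list(self.sample_ids),
            populations=dict(self.populations),
        )

    def subset_samples(self, sample_ids) -> "HaplotypePanel":
        sample_ids = list(sample_ids)
        rows = self.haplotype_rows(sample_ids)
        return HaplotypePanel(
            variants=list(self.variants),
            haplotypes=self.haplotypes[rows],
            sample_ids=sample_ids,
            populations={s: self.population_of(s) for s in sample_ids},
        )

    def drop_samples(self, sample_ids) -> "HaplotypePanel":
        drop = set(sample_ids)
        keep = [s for s in self.sample_ids if s not in drop]
        return self.subset_samples(keep)

    def variants_in_regions(self, regions) -> list[str]:
        """Ids of panel variants falling in any of the (flanked) regions."""
        out = []
        for v in self.variants:
            if any(r.contains(v.chrom, v.pos) for r in regions):
                out.append(v.id)
        return out


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls, entries in {0, 1, 2} with -1 for missing.

    Shape is (n_markers, n_samples), matching the on-disk TSV layout
    (one row per marker, one column per sample).
    """

    marker_ids: list[str]
    sample_ids: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.marker_ids), len(self.sample_ids)):
            raise PanelIOError("calls shape inconsistent with id lists")
        if self.calls.size and not np.isin(self.calls, (-1, 0, 1, 2)).all():
            raise PanelIOError("calls must be in {0,1,2} or -1 (missing)")
        self._midx = {m: i for i, m in enumerate(self.marker_ids)}
        self._sidx = {s: i for i, s in enumerate(self.sample_ids)}

    def marker_index(self, marker_id: str) -> int:
        return self._midx[marker_id]

    def sample_index(self, sample_id: str) -> int:
        return self._sidx[sample_id]

    def sample_column(self, sample_id: str) -> np.ndarray:
        return self.calls[:, self._sidx[sample_id]]


def panel_to_genotype_matrix(panel: HaplotypePanel) -> GenotypeMatrix:
    """Collapse phased haplotypes to diploid calls (markers x samples)."""
    return GenotypeMatrix(
        marker_ids=panel.variant_ids,
        sample_ids=list(panel.sample_ids),
        calls=panel.genotypes().T,
    )


# ---------------------------------------------------------------------------
# VCF


def read_vcf_panel(path, populations: dict[str, str] | None = None) -> HaplotypePanel:
    """Read a phased VCF into a :class:`HaplotypePanel`.

    Only biallelic records are kept; multiallelic records are skipped and
    the skip count logged.  Validation status is taken from a ``VS`` INFO
    field when present (``validated`` otherwise).  Any unphased or missing
    genotype raises :class:`UnphasedGenotypeError` naming the sample and
    position.

    Parameters
    ----------
    path : str or Path
        Uncompressed or bgzipped VCF with GT fields.
    populations : dict, optional
        sample id -> population label (e.g. YRI/ASN/EUR).
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    n_multiallelic = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            continue
        gts = rec.genotypes  # [[a, b, phased], ...]
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0 or not phased:
                raise UnphasedGenotypeError(
                    f"unphased or missing genotype for sample {samples[i]!r} "
                    f"at {rec.CHROM}:{rec.POS}"
                )
            col[2 * i] = a
            col[2 * i + 1] = b
        vs = rec.INFO.get("VS") or "validated"
        vid = rec.ID or f"{normalize_chrom(rec.CHROM)}:{rec.POS}"
        variants.append(
            Variant(
                id=vid,
                chrom=normalize_chrom(rec.CHROM),
                pos=rec.POS,
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                validation_status=vs,
            )
        )
        columns.append(col)
    vcf.close()
    if not variants:
        raise PanelIOError(f"no biallelic phased records in {path}")
    if n_multiallelic:
        log.info("skipped %d multiallelic records in %s", n_multiallelic, path)
    panel = HaplotypePanel(
        variants=variants,
        haplotypes=np.column_stack(columns),
        sample_ids=samples,
        populations=dict(populations or {}),
    )
    panel.n_multiallelic_skipped = n_multiallelic
    return panel


def write_panel(panel: HaplotypePanel, path) -> None:
    """Write a panel as an uncompressed phased VCF 4.2 file.

    Validation status is stored in the ``VS`` INFO field so that
    write/read round trips are lossless.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=VS,Number=1,Type=String,Description="Validation status">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in panel.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        H = panel.haplotypes
        for j, v in enumerate(panel.variants):
            gts = "\t".join(
                f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(panel.n_samples)
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\t.\tVS={v.validation_status}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# BED regions


def read_regions_bed(path, flank_bp: int = 0) -> list[Region]:
    """Read BED (3+ columns, 0-based half-open) into flanked Regions."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise PanelIOError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise PanelIOError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            regions.append(
                Region(chrom=chrom, start=start, end=end, name=name, flank_bp=flank_bp)
            )
    return regions


# ---------------------------------------------------------------------------
# Marker manifests and sample QC tables (TSV)


def read_marker_manifest(path) -> pd.DataFrame:
    """Read a marker manifest TSV into a validated DataFrame.

    Required columns: marker_id, probeset_id, classification,
    validation_status, call_rate.  One row per probeset.
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "probeset_id": str})
    return validate_marker_manifest(df)


def validate_marker_manifest(df: pd.DataFrame) -> pd.DataFrame:
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise PanelIOError(f"marker manifest missing required column {col!r}")
    bad_class = set(df["classification"].dropna()) - set(MARKER_CLASSIFICATIONS)
    if bad_class:
        raise PanelIOError(f"unknown classification labels: {sorted(bad_class)}")
    bad_vs = set(df["validation_status"].dropna()) - set(VALIDATION_STATUSES)
    if bad_vs:
        raise PanelIOError(f"unknown validation_status labels: {sorted(bad_vs)}")
    return df


def write_marker_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sample_table(path) -> pd.DataFrame:
    """Read a sample QC TSV (DQC, scan status, plate, control type)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "plate_id": str})
    for col in SAMPLE_TABLE_COLUMNS:
        if col not in df.columns:
            raise PanelIOError(f"sample table missing required column {col!r}")
    bad = set(df["control_type"].dropna()) - set(CONTROL_TYPES)
    if bad:
        raise PanelIOError(f"unknown control_type labels: {sorted(bad)}")
    df["scan_ok"] = df["scan_ok"].astype(bool)
    return df


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Genotype call matrices (TSV)


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read a marker x sample genotype TSV ('NA' encodes missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    calls = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING_CALL, calls).astype(np.int8)
    return GenotypeMatrix(
        marker_ids=[str(m) for m in df.index],
        sample_ids=[str(s) for s in df.columns],
        calls=calls,
    )


def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        gm.calls.astype(object), index=gm.marker_ids, columns=gm.sample_ids
    )
    df = df.mask(df == MISSING_CALL, "NA")
    df.index.name = "marker_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# JSON reports


def write_json_report(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
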