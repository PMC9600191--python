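"""Core data model for allelic-imbalance genomic-instability (GI) analysis.

The objects here mirror how a matched liquid-biopsy experiment is organised:
per-compartment variant call tables (leukocyte reference, CSF, plasma,
optional tumor tissue) grouped per patient, plus the clinical record used by
the survival layer.  Allele-specific copy-number truth (``CNASegment`` /
``CNAProfile``) and binned read-count tracks (``BinTrack``) support the
simulation and the copy-number validation arm respectively.

Coordinate conventions: variant positions are 1-based (VCF convention);
copy-number segments and bins are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

COMPARTMENTS = ("leukocyte", "plasma", "csf", "tissue")
VARIANT_KINDS = ("SNV", "indel", "CNV")
STATUSES = ("GI", "GS")


class ConfigError(ValueError):
    """Invalid configuration (bad threshold, missing input, malformed option)."""


class DataError(ValueError):
    """Invalid or inconsistent data (malformed file, broken invariant)."""


VariantKey = tuple[str, int, str, str]


@dataclass
class VariantRecord:
    """One called variant in one sample.

    ``af`` is the ALT allele fraction; for SNV/indel records with read depths
    it equals ``alt_depth / total_depth``.  CNV records carry ``copy_number``
    instead of depths/AF.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    kind: str = "SNV"
    gene: Optional[str] = None
    alt_depth: Optional[int] = None
    total_depth: Optional[int] = None
    af: Optional[float] = None
    copy_number: Optional[float] = None

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    def validate(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos} at {self.key}")
        if self.kind not in VARIANT_KINDS:
            raise DataError(f"unknown variant kind {self.kind!r} at {self.key}")
        if self.kind == "CNV":
            if self.copy_number is None or self.copy_number < 0:
                raise DataError(f"CNV record requires copy_number >= 0 at {self.key}")
            return
        if self.alt_depth is not None and self.total_depth is not None:
            if not (0 <= self.alt_depth <= self.total_depth):
                raise DataError(
                    f"depths out of order at {self.key}: "
                    f"alt={self.alt_depth} total={self.total_depth}"
                )
            if self.af is not None and self.total_depth > 0:
                if abs(self.af - self.alt_depth / self.total_depth) > 0.01:
                    raise DataError(
                        f"af disagrees with depths by > 0.01 at {self.key}"
                    )
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise DataError(f"af outside [0, 1] at {self.key}: {self.af}")


@dataclass
class VariantTable:
    """All variant records called in one sample of one compartment."""

    sample_id: str
    patient_id: str
    compartment: str
    records: list[VariantRecord] = field(default_factory=list)

    def validate(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise DataError(
                f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}"
            )
        seen: set[VariantKey] = set()
        for rec in self.records:
            rec.validate()
            if rec.key in seen:
                raise DataError(
                    f"duplicate variant key {rec.key} in sample {self.sample_id}"
                )
            seen.add(rec.key)

    def key_set(self) -> set[VariantKey]:
        return {rec.key for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, records: list[VariantRecord]) -> "VariantTable":
        return replace(self, records=records)


@dataclass
class ClinicalRecord:
    """Per-patient clinical covariates and survival endpoints.

    Times are in years.  ``mfs`` is meningeal-metastasis-free survival,
    ``os`` overall survival; the event flags are False for censored patients.
    """

    patient_id: str
    sex: str  # "F" | "M"
    age: float
    primary_tumor: str
    kps: int
    icp_kpa: float
    lp_shunt: bool
    mfs_time: float
    mfs_event: bool
    os_time: float
    os_event: bool

    def validate(self) -> None:
        if self.kps % 10 != 0 or not (0 <= self.kps <= 100):
            raise DataError(f"KPS must be a multiple of 10 in [0, 100]: {self.kps}")
        if self.icp_kpa <= 0:
            raise DataError(f"intracranial pressure must be > 0: {self.icp_kpa}")
        if self.mfs_time < 0 or self.os_time < 0:
            raise DataError("survival times must be >= 0")


@dataclass
class PatientSampleSet:
    """Matched sample tables plus the clinical record for one patient.

    The leukocyte table is mandatory: it is the germline reference every
    assay compartment is scored against.
    """

    patient_id: str
    leukocyte: VariantTable
    csf: Optional[VariantTable] = None
    plasma: Optional[VariantTable] = None
    tissue: Optional[VariantTable] = None
    clinical: Optional[ClinicalRecord] = None

    def validate(self) -> None:
        if self.leukocyte is None:
            raise DataError(f"patient {self.patient_id}: leukocyte table required")
        for tab in (self.leukocyte, self.csf, self.plasma, self.tissue):
            if tab is not None and tab.patient_id != self.patient_id:
                raise DataError(
                    f"table {tab.sample_id} belongs to {tab.patient_id}, "
                    f"not {self.patient_id}"
                )

    def assay_tables(self) -> dict[str, VariantTable]:
        """Non-reference tables keyed by compartment, in a fixed order."""
        out = {}
        for comp in ("csf", "plasma", "tissue"):
            tab = getattr(self, comp)
            if tab is not None:
                out[comp] = tab
        return out


@dataclass
class SharedMutation:
    """A germline het variant found in both the leukocyte reference and one
    assay sample, carrying both allele fractions."""

    key: VariantKey
    leukocyte_af: float
    sample_af: float
    alt_depth: Optional[int] = None
    total_depth: Optional[int] = None


@dataclass
class GIResult:
    """The per-sample GI statistic: score = n_gi / n_common.

    ``n_common`` counts shared germline het mutations, ``n_gi`` those whose
    sample AF falls outside the quartile band around 0.5.  ``score`` is None
    (and status "indeterminate") when ``n_common`` is below the minimum.
    """

    patient_id: str
    sample_id: str
    compartment: str
    n_common: int
    n_gi: int
    score: Optional[float] = None
    status: Optional[str] = None
    cutoff_used: Optional[float] = None

    def validate(self) -> None:
        if not (0 <= self.n_gi <= self.n_common):
            raise DataError(
                f"n_gi must lie in [0, n_common]: {self.n_gi}/{self.n_common}"
            )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise DataError(f"score outside [0, 1]: {self.score}")


@dataclass(frozen=True)
class CNASegment:
    """Allele-specific copy-number state over a genomic interval.

    ``c_major >= c_minor >= 0`` are integer copies of the two parental
    haplotypes in the aberrant clone; (1, 1) is the diploid state.
    """

    chrom: str
    start: int  # 0-based
    end: int  # half-open
    c_major: int
    c_minor: int

    def validate(self) -> None:
        if self.start >= self.end:
            raise DataError(f"segment start must be < end: {self}")
        if not (self.c_major >= self.c_minor >= 0):
            raise DataError(f"require c_major >= c_minor >= 0: {self}")

    @property
    def total_cn(self) -> int:
        return self.c_major + self.c_minor

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CNAProfile:
    """A clone's copy-number profile mixed into cfDNA at tumor fraction f."""

    segments: list[CNASegment]
    tumor_fraction: float

    def validate(self) -> None:
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise DataError(f"tumor fraction outside [0, 1]: {self.tumor_fraction}")
        by_chrom: dict[str, list[CNASegment]] = {}
        for seg in self.segments:
            seg.validate()
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if a.end > b.start:
                    raise DataError(f"overlapping segments on {chrom}: {a} / {b}")

    @property
    def is_diploid(self) -> bool:
        return all(s.c_major == 1 and s.c_minor == 1 for s in self.segments)

    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    def locate(self, chrom: str, pos: int) -> CNASegment:
        """Segment containing the 1-based position ``pos`` (error if none)."""
        for seg in self.segments:
            if seg.chrom == chrom and seg.start < pos <= seg.end:
                return seg
        raise DataError(f"site {chrom}:{pos} falls outside all segments")


@dataclass
class BinTrack:
    """Binned read counts over the genome, with optional log2 ratios.

    ``bins`` has columns chrom, start, end, raw_count and (after
    normalisation) log2_ratio; intervals are 0-based half-open.
    """

    sample_id: str
    bins: pd.DataFrame
    bin_size: int

    def validate(self) -> None:
        required = {"chrom", "start", "end", "raw_count"}
        missing = required - set(self.bins.columns)
        if missing:
            raise DataError(f"bin track missing columns: {sorted(missing)}")
        if (self.bins["raw_count"] < 0).any():
            raise DataError("negative bin counts")


@dataclass
class CNVCallSummary:
    """Segmented copy-number calls and the altered-genome fraction (AGF)."""

    sample_id: str
    segments: pd.DataFrame  # chrom, start, end, n_bins, mean_log2
    altered_genome_fraction: float
    gi_concordant: Optional[bool] = None


@dataclass
class CutoffModel:
    """A fitted (or fixed) GI/GS score threshold.

    For the two-component Gaussian mixture method the component parameters
    are retained; ``fallback`` records a degenerate fit that was resolved by
    the Otsu criterion instead.
    """

    method: str  # "mixture" | "otsu" | "fixed"
    cutoff: float
    means: Optional[tuple[float, float]] = None
    sds: Optional[tuple[float, float]] = None
    weights: Optional[tuple[float, float]] = None
    rng_seed: Optional[int] = None
    fallback: bool = False

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "cutoff": float(self.cutoff),
            "means": list(self.means) if self.means else None,
            "sds": list(self.sds) if self.sds else None,
            "weights": list(self.weights) if self.weights else None,
            "rng_seed": self.rng_seed,
            "fallback": self.fallback,
        }
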