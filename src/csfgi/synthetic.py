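"""Synthetic cohort generator for the allelic-imbalance GI pipeline.

The generator emulates the statistical structure the score detects, end to
end: germline heterozygous SNPs with allele fraction centred at 0.5 in
leukocytes; an aberrant clone with allele-specific copy-number alterations
shared by a patient's CSF, plasma and tissue compartments but mixed in at
compartment-specific tumor fractions; binomial read sampling at panel-like
depths; Poisson bin counts for the low-depth WGS validation arm; somatic
driver mutations whose rates differ by genomic status; and clinical
covariates and exponential survival times driven by the true GI burden.

The AF mixing model: at a het site inside a segment with allele-specific
copies (c_major, c_minor), with the ALT allele on a haplotype carrying
``c_alt`` copies, the expected ALT fraction in cfDNA at tumor fraction f is

    p = ((1 - f) * 1 + f * c_alt) / ((1 - f) * 2 + f * (c_major + c_minor))

which reduces to 0.5 at f = 0 and to c_alt / (c_major + c_minor) at f = 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import default_genome
from .models import (
    CNAProfile,
    CNASegment,
    ClinicalRecord,
    ConfigError,
    DataError,
    PatientSampleSet,
    VariantRecord,
    VariantTable,
)
from .variant_io import (
    write_clinical_table,
    write_variant_table,
)
from .models import BinTrack

BASES = ("A", "C", "G", "T")

#: driver genes with approximate genomic positions used by the somatic layer
DRIVER_GENES: dict[str, tuple[str, int]] = {
    "TP53": ("chr17", 7_670_000),
    "EGFR": ("chr7", 55_100_000),
    "RB1": ("chr13", 48_300_000),
    "ERBB2": ("chr17", 39_700_000),
    "KMT2C": ("chr7", 151_900_000),
    "CDKN2A": ("chr9", 21_970_000),
    "APC": ("chr5", 112_700_000),
    "RICTOR": ("chr5", 38_900_000),
    "FGFR1": ("chr8", 38_400_000),
    "PIK3CA": ("chr3", 179_200_000),
    "MDM2": ("chr12", 69_200_000),
}

#: allele-specific copy-number states available to an unstable clone, with
#: sampling weights.  Because the two haplotype AFs at a het site sum to 1,
#: both flip outside the quartile band at the same tumor-fraction threshold,
#: which depends on the state: (3,0) flips above f = 0.4, (4,0) above 1/3,
#: (5,1) and copy-neutral LOH (2,0) above 0.5.  The default mix holds only
#: states detectable across the default CSF tumor-fraction range; balanced
#: gains (e.g. (3,1)) and hemizygous deletions (1,0) — blind spots of the
#: AF score — can be added through the config.
DEFAULT_CNA_STATES: tuple[tuple[tuple[int, int], float], ...] = (
    ((3, 0), 0.35),
    ((4, 0), 0.25),
    ((5, 1), 0.25),
    ((2, 0), 0.15),
)

PRIMARY_TUMOR_FREQS = {
    "LUAD": 45 / 56,
    "BRCA": 7 / 56,
    "COAD": 1 / 56,
    "LUSC": 1 / 56,
    "SCLC": 1 / 56,
    "STAD": 1 / 56,
}


@dataclass
class SimulationConfig:
    """All knobs of the generator, with cohort-scale defaults.

    Tumor-fraction ranges are per compartment for genomically unstable
    (GI) patients; genome-stable (GS) patients carry a diploid clone, so
    their het AFs stay at 0.5 regardless of tumor fraction.  Survival is
    exponential with the GS-group medians as baseline and a proportional
    hazard multiplier for GI patients; censoring is administrative,
    uniform over [0, censor_horizon].
    """

    n_patients: int = 56
    n_plasma: int = 50
    n_tissue: int = 9
    gi_prevalence: float = 0.661
    n_het_sites: int = 300

    depth_means: dict = field(
        default_factory=lambda: {
            "leukocyte": 800.0,
            "plasma": 1000.0,
            "csf": 1500.0,
            "tissue": 1000.0,
        }
    )
    depth_dispersion: Optional[float] = None  # negative-binomial size; None = Poisson

    csf_tf_range: tuple[float, float] = (0.55, 0.95)
    plasma_tf_range: tuple[float, float] = (0.0, 0.05)
    tissue_tf_range: tuple[float, float] = (0.55, 0.95)
    gs_csf_tf_range: tuple[float, float] = (0.1, 0.6)
    #: probability that a GI patient's extracranial disease sheds strongly
    #: into plasma (plasma then draws its tumor fraction from the CSF range)
    plasma_high_shed_prob: float = 0.08
    agf_range: tuple[float, float] = (0.2, 0.5)
    cna_states: tuple = DEFAULT_CNA_STATES
    artifact_rate: float = 0.0

    driver_probs_gi: dict = field(
        default_factory=lambda: {
            "TP53": 0.75, "EGFR": 0.50, "RB1": 0.35, "ERBB2": 0.30,
            "KMT2C": 0.30, "CDKN2A": 0.25, "APC": 0.20, "RICTOR": 0.20,
        }
    )
    driver_probs_gs: dict = field(
        default_factory=lambda: {
            "TP53": 0.30, "EGFR": 0.35, "RB1": 0.10, "ERBB2": 0.08,
            "KMT2C": 0.08, "CDKN2A": 0.10, "APC": 0.10, "RICTOR": 0.10,
        }
    )
    somatic_af_detect: float = 0.02
    cnv_detect_delta: float = 0.5

    icp_baseline_kpa: float = 1.3
    beta_icp: float = 2.0
    sigma_icp: float = 0.8
    shunt_threshold_kpa: float = 2.5
    kps_baseline: float = 80.0
    beta_kps: float = 40.0
    sigma_kps: float = 12.0

    mfs_median_gs: float = 2.9
    os_median_gs: float = 3.9
    hr_mfs: float = 2.338
    hr_os: float = 2.109
    censor_horizon: float = 10.0

    genome: Optional[dict] = None
    bin_size: int = 1_000_000
    wgs_mean_bin_count: float = 1000.0

    rng_seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.gi_prevalence <= 1.0):
            raise ConfigError(f"gi_prevalence outside [0, 1]: {self.gi_prevalence}")
        if self.n_patients < 1 or self.n_het_sites < 1:
            raise ConfigError("n_patients and n_het_sites must be >= 1")
        for comp, mean in self.depth_means.items():
            if mean <= 0:
                raise ConfigError(f"depth mean for {comp} must be > 0")
        for name in ("csf_tf_range", "plasma_tf_range", "tissue_tf_range",
                     "gs_csf_tf_range", "agf_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigError(f"{name} must satisfy 0 <= lo <= hi <= 1")
        if self.mfs_median_gs <= 0 or self.os_median_gs <= 0:
            raise ConfigError("baseline survival medians must be > 0")
        if self.hr_mfs <= 0 or self.hr_os <= 0:
            raise ConfigError("hazard ratios must be > 0")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ConfigError("artifact_rate outside [0, 1]")

    def resolved_genome(self) -> dict[str, int]:
        return dict(self.genome) if self.genome else default_genome()


@dataclass(frozen=True)
class HetSite:
    """A germline heterozygous site: position, alleles, and which parental
    haplotype carries the ALT allele (a property of the patient, shared by
    every compartment)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: Optional[str] = None
    alt_on_major: bool = True


# ---------------------------------------------------------------------------
# Copy-number profiles

def diploid_segments(genome: dict[str, int]) -> list[CNASegment]:
    return [CNASegment(c, 0, n, 1, 1) for c, n in genome.items()]


def simulate_clone_segments(
    config: SimulationConfig, status: str, rng: np.random.Generator
) -> list[CNASegment]:
    """Draw a clone's copy-number profile; GS clones are diploid.

    For a GI clone, a target altered-genome fraction is drawn from
    ``agf_range`` and each chromosome is altered with that probability,
    receiving a random allele-specific state from ``cna_states``.
    """
    genome = config.resolved_genome()
    if status == "GS":
        return diploid_segments(genome)
    if status != "GI":
        raise ConfigError(f"unknown genomic status {status!r} (expected GI or GS)")
    target_agf = rng.uniform(*config.agf_range)
    states = [s for s, _ in config.cna_states]
    weights = np.array([w for _, w in config.cna_states], dtype=float)
    weights /= weights.sum()
    segments = []
    altered_any = False
    chroms = list(genome)
    for chrom in chroms:
        if rng.random() < target_agf:
            cmaj, cmin = states[rng.choice(len(states), p=weights)]
            segments.append(CNASegment(chrom, 0, genome[chrom], cmaj, cmin))
            altered_any = True
        else:
            segments.append(CNASegment(chrom, 0, genome[chrom], 1, 1))
    if not altered_any:  # a GI clone must alter something; force one chromosome
        i = int(rng.integers(len(chroms)))
        cmaj, cmin = states[rng.choice(len(states), p=weights)]
        chrom = chroms[i]
        segments[i] = CNASegment(chrom, 0, genome[chrom], cmaj, cmin)
    return segments


def _draw_tumor_fraction(
    config: SimulationConfig, status: str, compartment: str, rng: np.random.Generator
) -> float:
    if compartment == "leukocyte":
        return 0.0
    if status == "GS":
        # GS patients still shed tumor DNA (their clone is just diploid)
        return float(rng.uniform(*config.gs_csf_tf_range)) if compartment != "plasma" \
            else float(rng.uniform(*config.plasma_tf_range))
    if compartment == "csf":
        return float(rng.uniform(*config.csf_tf_range))
    if compartment == "tissue":
        return float(rng.uniform(*config.tissue_tf_range))
    if compartment == "plasma":
        if rng.random() < config.plasma_high_shed_prob:
            return float(rng.uniform(*config.csf_tf_range))
        return float(rng.uniform(*config.plasma_tf_range))
    raise ConfigError(f"unknown compartment {compartment!r}")


def simulate_cna_profile(
    config: SimulationConfig, status: str, compartment: str, rng: np.random.Generator
) -> CNAProfile:
    """One compartment's cfDNA copy-number mixture (clone + tumor fraction)."""
    config.validate()
    segments = simulate_clone_segments(config, status, rng)
    f = _draw_tumor_fraction(config, status, compartment, rng)
    profile = CNAProfile(segments=segments, tumor_fraction=f)
    profile.validate()
    return profile


# ---------------------------------------------------------------------------
# Allele-fraction mixing

def expected_alt_af(profile: CNAProfile, site: HetSite) -> float:
    """Expected ALT allele fraction at a het site under the mixing model."""
    seg = profile.locate(site.chrom, site.pos)
    f = profile.tumor_fraction
    c_alt = seg.c_major if site.alt_on_major else seg.c_minor
    denom = (1.0 - f) * 2.0 + f * (seg.c_major + seg.c_minor)
    if denom == 0.0:  # pure clone, homozygous deletion: no DNA at the site
        raise DataError(f"no cfDNA at site {site.chrom}:{site.pos} (f=1, CN 0)")
    return ((1.0 - f) * 1.0 + f * c_alt) / denom


def expected_gi_score(
    profile: CNAProfile, band: tuple[float, float] = (0.25, 0.75)
) -> float:
    """Length-weighted expected fraction of het sites outside the AF band.

    The ALT haplotype is major or minor with probability 1/2, so each
    segment contributes half of each haplotype's indicator.
    """
    f = profile.tumor_fraction
    lo, hi = band
    total = profile.total_length()
    acc = 0.0
    for seg in profile.segments:
        denom = (1.0 - f) * 2.0 + f * seg.total_cn
        if denom == 0.0:
            continue
        outside = 0.0
        for c_alt in (seg.c_major, seg.c_minor):
            p = ((1.0 - f) + f * c_alt) / denom
            if p < lo or p > hi:
                outside += 0.5
        acc += seg.length * outside
    return acc / total if total else 0.0


# ---------------------------------------------------------------------------
# Sites and read sampling

def simulate_het_sites(
    config: SimulationConfig, rng: np.random.Generator
) -> list[HetSite]:
    """Panel-like germline het sites, placed uniformly over the genome
    (chromosomes weighted by length), with per-site ALT haplotype choice."""
    genome = config.resolved_genome()
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    sites: list[HetSite] = []
    used: set[tuple[str, int]] = set()
    while len(sites) < config.n_het_sites:
        ci = int(rng.choice(len(chroms), p=probs))
        chrom = chroms[ci]
        pos = int(rng.integers(1, genome[chrom] + 1))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref, alt = rng.choice(len(BASES), size=2, replace=False)
        sites.append(
            HetSite(
                chrom=chrom,
                pos=pos,
                ref=BASES[ref],
                alt=BASES[alt],
                gene=f"PNL{len(sites):04d}",
                alt_on_major=bool(rng.random() < 0.5),
            )
        )
    return sites


def _draw_depths(
    mean: float, n: int, rng: np.random.Generator, dispersion: Optional[float]
) -> np.ndarray:
    if dispersion is None:
        depths = rng.poisson(mean, size=n)
    else:
        # negative binomial with mean `mean` and size (shape) `dispersion`
        p = dispersion / (dispersion + mean)
        depths = rng.negative_binomial(dispersion, p, size=n)
    return np.maximum(depths, 1)


def simulate_sample_variants(
    profile: CNAProfile,
    sites: Sequence[HetSite],
    depth_mean: float,
    rng: np.random.Generator,
    *,
    sample_id: str = "sample",
    patient_id: str = "patient",
    compartment: str = "csf",
    dispersion: Optional[float] = None,
    artifact_rate: float = 0.0,
) -> VariantTable:
    """Binomially sample read counts at het sites under the mixing model.

    Every site must fall inside exactly one profile segment.  Depth is
    Poisson (or negative-binomial) around ``depth_mean``; the ALT depth is
    binomial at the site's expected AF.  With probability ``artifact_rate``
    a site's AF is replaced by an artifact draw far from 0.5, emulating the
    mapping/sequencing noise floor of real panels.
    """
    if depth_mean <= 0:
        raise ConfigError(f"depth mean must be > 0, got {depth_mean}")
    ps = np.array([expected_alt_af(profile, s) for s in sites])
    if artifact_rate > 0:
        hit = rng.random(len(ps)) < artifact_rate
        n_hit = int(hit.sum())
        if n_hit:
            low = rng.uniform(0.0, 0.2, size=n_hit)
            high = rng.uniform(0.8, 1.0, size=n_hit)
            ps[hit] = np.where(rng.random(n_hit) < 0.5, low, high)
    depths = _draw_depths(depth_mean, len(ps), rng, dispersion)
    alts = rng.binomial(depths, ps)
    records = [
        VariantRecord(
            chrom=s.chrom,
            pos=s.pos,
            ref=s.ref,
            alt=s.alt,
            kind="SNV",
            gene=s.gene,
            alt_depth=int(a),
            total_depth=int(d),
            af=int(a) / int(d),
        )
        for s, a, d in zip(sites, alts, depths)
    ]
    table = VariantTable(
        sample_id=sample_id,
        patient_id=patient_id,
        compartment=compartment,
        records=records,
    )
    table.validate()
    return table


# ---------------------------------------------------------------------------
# WGS bins

def simulate_wgs_bins(
    profile: CNAProfile,
    genome: dict[str, int],
    bin_size: int,
    mean_bin_count: float,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> BinTrack:
    """Poisson bin counts proportional to the mixed total copy number.

    Expected count per bin is ``mean_bin_count * ((1-f)*2 + f*CN_total)/2``
    for the segment covering the bin.
    """
    if bin_size <= 0:
        raise ConfigError("bin_size must be > 0")
    f = profile.tumor_fraction
    cn_by_chrom: dict[str, list[CNASegment]] = {}
    for seg in profile.segments:
        cn_by_chrom.setdefault(seg.chrom, []).append(seg)
    rows = []
    for chrom, length in genome.items():
        segs = sorted(cn_by_chrom.get(chrom, []), key=lambda s: s.start)
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            mid = (start + end) // 2
            cn = 2
            for seg in segs:
                if seg.start <= mid < seg.end:
                    cn = seg.total_cn
                    break
            lam = mean_bin_count * ((1.0 - f) * 2.0 + f * cn) / 2.0
            rows.append((chrom, start, end, int(rng.poisson(lam))))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "raw_count"])
    track = BinTrack(sample_id=sample_id, bins=bins, bin_size=bin_size)
    track.validate()
    return track


# ---------------------------------------------------------------------------
# Clinical and survival

def _exponential_time(median: float, hazard_mult: float, rng: np.random.Generator) -> float:
    lam = np.log(2.0) / median * hazard_mult
    return float(rng.exponential(1.0 / lam))


def simulate_clinical(
    status: str,
    gi_score: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str = "patient",
) -> ClinicalRecord:
    """Clinical covariates and survival endpoints driven by the GI burden.

    log intracranial pressure rises linearly with the true GI score; an LP
    shunt is placed when the pressure exceeds the 2.5 kPa threshold.  KPS
    falls linearly with the score (rounded to tens).  Survival times are
    exponential with GS-group baseline medians and a proportional-hazard
    multiplier for GI patients, censored administratively.
    """
    if not (0.0 <= gi_score <= 1.0):
        raise ConfigError(f"gi_score outside [0, 1]: {gi_score}")
    sex = "M" if rng.random() < 27 / 56 else "F"
    age = float(np.clip(rng.normal(55.0, 12.0), 25.0, 85.0))
    tumors = list(PRIMARY_TUMOR_FREQS)
    tumor = tumors[rng.choice(len(tumors), p=list(PRIMARY_TUMOR_FREQS.values()))]

    icp = config.icp_baseline_kpa * float(
        np.exp(config.beta_icp * gi_score + rng.normal(0.0, config.sigma_icp))
    )
    lp_shunt = icp > config.shunt_threshold_kpa
    kps_raw = config.kps_baseline - config.beta_kps * gi_score + rng.normal(
        0.0, config.sigma_kps
    )
    kps = int(np.clip(round(kps_raw / 10.0) * 10, 10, 100))

    hr_mfs = config.hr_mfs if status == "GI" else 1.0
    hr_os = config.hr_os if status == "GI" else 1.0
    t_mfs = _exponential_time(config.mfs_median_gs, hr_mfs, rng)
    t_os = _exponential_time(config.os_median_gs, hr_os, rng)
    c_mfs = float(rng.uniform(0.0, config.censor_horizon))
    c_os = float(rng.uniform(0.0, config.censor_horizon))

    rec = ClinicalRecord(
        patient_id=patient_id,
        sex=sex,
        age=age,
        primary_tumor=tumor,
        kps=kps,
        icp_kpa=icp,
        lp_shunt=lp_shunt,
        mfs_time=min(t_mfs, c_mfs),
        mfs_event=t_mfs <= c_mfs,
        os_time=min(t_os, c_os),
        os_event=t_os <= c_os,
    )
    rec.validate()
    return rec


def simulate_survival_arms(
    n_per_arm: int,
    median_baseline: float = 2.9,
    hazard_ratio: float = 2.338,
    censor_horizon: float = 10.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Two-arm exponential survival data with a known hazard ratio.

    Returns a frame with columns time, event, group (0 = baseline arm,
    1 = elevated-hazard arm); used for hazard-ratio recovery checks.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    for group, mult in ((0, 1.0), (1, hazard_ratio)):
        lam = np.log(2.0) / median_baseline * mult
        t = rng.exponential(1.0 / lam, size=n_per_arm)
        c = rng.uniform(0.0, censor_horizon, size=n_per_arm)
        rows.append(
            pd.DataFrame(
                {
                    "time": np.minimum(t, c),
                    "event": t <= c,
                    "group": group,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_score_cohort(
    n_gs: int = 19,
    n_gi: int = 37,
    gs_mean: float = 0.03,
    gs_sd: float = 0.01,
    gi_mean: float = 0.28,
    gi_sd: float = 0.08,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bimodal score draws matching the cohort-scale score distribution
    (GS cluster near 0.03, GI cluster near 0.28), truncated to [0, 1].

    Returns (scores, labels) with labels 0 = GS, 1 = GI.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    gs = np.clip(rng.normal(gs_mean, gs_sd, size=n_gs), 0.0, 1.0)
    gi = np.clip(rng.normal(gi_mean, gi_sd, size=n_gi), 0.0, 1.0)
    scores = np.concatenate([gs, gi])
    labels = np.concatenate([np.zeros(n_gs, dtype=int), np.ones(n_gi, dtype=int)])
    return scores, labels


# ---------------------------------------------------------------------------
# Whole patients and cohorts

@dataclass
class CohortDataset:
    """An in-memory synthetic cohort plus (optionally) its on-disk layout."""

    config: SimulationConfig
    patients: list[PatientSampleSet]
    truth: dict
    csf_bins: dict[str, BinTrack]
    out_dir: Optional[Path] = None
    manifest_path: Optional[Path] = None
    clinical_path: Optional[Path] = None
    truth_path: Optional[Path] = None


def _somatic_records(
    config: SimulationConfig,
    drivers: dict[str, bool],
    tumor_fraction: float,
    depth_mean: float,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Somatic driver SNVs at clonal heterozygous dosage f/2, subject to a
    simple detection rule (AF and ALT-read thresholds)."""
    records = []
    for gene, present in drivers.items():
        if not present:
            continue
        chrom, pos = DRIVER_GENES[gene]
        p_som = tumor_fraction / 2.0
        depth = int(_draw_depths(depth_mean, 1, rng, config.depth_dispersion)[0])
        alt = int(rng.binomial(depth, min(p_som, 1.0)))
        if alt < 4 or alt / depth < config.somatic_af_detect:
            continue
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref="C",
                alt="T",
                kind="SNV",
                gene=gene,
                alt_depth=alt,
                total_depth=depth,
                af=alt / depth,
            )
        )
    return records


def _cnv_records(
    config: SimulationConfig,
    segments: Sequence[CNASegment],
    tumor_fraction: float,
) -> list[VariantRecord]:
    """Per-gene CNV calls: observed mixture copy number where it deviates
    from diploid by at least the detection delta."""
    records = []
    f = tumor_fraction
    for gene, (chrom, pos) in DRIVER_GENES.items():
        for seg in segments:
            if seg.chrom == chrom and seg.start < pos <= seg.end:
                obs = (1.0 - f) * 2.0 + f * seg.total_cn
                if abs(obs - 2.0) >= config.cnv_detect_delta:
                    records.append(
                        VariantRecord(
                            chrom=chrom,
                            pos=pos + 1,  # offset from the SNV hotspot key
                            ref="N",
                            alt="<CNV>",
                            kind="CNV",
                            gene=gene,
                            copy_number=round(obs, 3),
                        )
                    )
                break
    return records


def simulate_patient(
    config: SimulationConfig,
    patient_id: str,
    rng: np.random.Generator,
    with_plasma: bool = True,
    with_tissue: bool = False,
) -> tuple[PatientSampleSet, dict, BinTrack]:
    """One patient: status, clone, matched tables, clinical record, bins."""
    status = "GI" if rng.random() < config.gi_prevalence else "GS"
    sites = simulate_het_sites(config, rng)
    clone = simulate_clone_segments(config, status, rng)
    genome = config.resolved_genome()
    total_len = sum(genome.values())
    altered_len = sum(
        s.length for s in clone if not (s.c_major == 1 and s.c_minor == 1)
    )

    probs = config.driver_probs_gi if status == "GI" else config.driver_probs_gs
    drivers = {g: bool(rng.random() < p) for g, p in probs.items()}

    compartments = ["leukocyte", "csf"]
    if with_plasma:
        compartments.append("plasma")
    if with_tissue:
        compartments.append("tissue")

    tables: dict[str, VariantTable] = {}
    tfs: dict[str, float] = {}
    for comp in compartments:
        f = _draw_tumor_fraction(config, status, comp, rng)
        segs = diploid_segments(genome) if comp == "leukocyte" else clone
        profile = CNAProfile(segments=segs, tumor_fraction=f)
        table = simulate_sample_variants(
            profile,
            sites,
            config.depth_means[comp],
            rng,
            sample_id=f"{patient_id}_{comp}",
            patient_id=patient_id,
            compartment=comp,
            dispersion=config.depth_dispersion,
            artifact_rate=config.artifact_rate if comp != "leukocyte" else 0.0,
        )
        if comp != "leukocyte":
            table.records.extend(
                _somatic_records(config, drivers, f, config.depth_means[comp], rng)
            )
            table.records.extend(_cnv_records(config, clone, f))
            table.validate()
        tables[comp] = table
        tfs[comp] = f

    csf_profile = CNAProfile(segments=clone, tumor_fraction=tfs["csf"])
    true_score = expected_gi_score(csf_profile)
    clinical = simulate_clinical(status, true_score, config, rng, patient_id)

    bins = simulate_wgs_bins(
        csf_profile,
        genome,
        config.bin_size,
        config.wgs_mean_bin_count,
        rng,
        sample_id=f"{patient_id}_csf",
    )

    pset = PatientSampleSet(
        patient_id=patient_id,
        leukocyte=tables["leukocyte"],
        csf=tables["csf"],
        plasma=tables.get("plasma"),
        tissue=tables.get("tissue"),
        clinical=clinical,
    )
    pset.validate()
    truth = {
        "status": status,
        "tumor_fractions": {k: round(v, 6) for k, v in tfs.items()},
        "true_agf": round(altered_len / total_len, 6),
        "expected_csf_score": round(true_score, 6),
        "drivers": {g: v for g, v in drivers.items() if v},
        "segments": [
            {
                "chrom": s.chrom, "start": s.start, "end": s.end,
                "c_major": s.c_major, "c_minor": s.c_minor,
            }
            for s in clone
            if not (s.c_major == 1 and s.c_minor == 1)
        ],
    }
    return pset, truth, bins


def simulate_cohort(
    config: SimulationConfig, out_dir: Optional[str | Path] = None
) -> CohortDataset:
    """Generate a full cohort; optionally write every artifact to disk.

    On-disk layout: ``variants/<sample>.vcf`` + ``.tsv`` mirrors,
    ``bins/<patient>_csf_bins.tsv``, ``manifest.csv``, ``clinical.csv`` and
    ``ground_truth.json``.  Outputs are byte-identical across runs with the
    same config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    patients: list[PatientSampleSet] = []
    truth: dict = {}
    csf_bins: dict[str, BinTrack] = {}
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        pset, ptruth, bins = simulate_patient(
            config,
            pid,
            rng,
            with_plasma=i < config.n_plasma,
            with_tissue=i < config.n_tissue,
        )
        patients.append(pset)
        truth[pid] = ptruth
        csf_bins[pid] = bins

    dataset = CohortDataset(
        config=config, patients=patients, truth=truth, csf_bins=csf_bins
    )
    if out_dir is not None:
        _write_cohort(dataset, Path(out_dir))
    return dataset


def _write_cohort(dataset: CohortDataset, out_dir: Path) -> None:
    from .cnv_profile import write_bin_track

    out_dir.mkdir(parents=True, exist_ok=True)
    var_dir = out_dir / "variants"
    bin_dir = out_dir / "bins"
    manifest_rows = []
    for pset in dataset.patients:
        for comp in ("leukocyte", "csf", "plasma", "tissue"):
            table = getattr(pset, comp)
            if table is None:
                continue
            vcf_path = var_dir / f"{table.sample_id}.vcf"
            write_variant_table(table, vcf_path, format="vcf")
            write_variant_table(table, var_dir / f"{table.sample_id}.tsv", format="tsv")
            manifest_rows.append(
                {
                    "patient_id": pset.patient_id,
                    "sample_id": table.sample_id,
                    "compartment": comp,
                    "path": str(vcf_path.relative_to(out_dir)),
                }
            )
    for pid, track in dataset.csf_bins.items():
        write_bin_track(track, bin_dir / f"{pid}_csf_bins.tsv")

    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    clinical_path = write_clinical_table(
        [p.clinical for p in dataset.patients if p.clinical], out_dir / "clinical.csv"
    )
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(dataset.truth, indent=2, sort_keys=True) + "\n")

    dataset.out_dir = out_dir
    dataset.manifest_path = manifest_path
    dataset.clinical_path = clinical_path
    dataset.truth_path = truth_path


def load_ground_truth(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataError(f"ground-truth file not found: {path}")
    return json.loads(path.read_text())
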