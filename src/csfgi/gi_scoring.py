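"""The GI score: allelic imbalance of shared germline het variants.

A germline heterozygous SNP or indel has a theoretical allele fraction of
0.5 in a diploid genome.  Tumor-derived cfDNA carrying allele-specific
copy-number alterations pulls the observed AF away from 0.5; the further a
sample's shared germline hets deviate, the more genomically unstable the
DNA it contains.  The per-sample statistic is

    GI score = N_GI / N_common

where N_common counts germline het mutations shared between the leukocyte
reference and the assay sample (leukocyte AF within [0.2, 0.8]), and N_GI
counts those whose assay AF lies outside the theoretical quartile band,
i.e. AF < 0.25 or AF > 0.75.  Boundary convention: the band edges 0.25 and
0.75 are *not* GI; the leukocyte filter bounds 0.2 and 0.8 *are* retained.

Copy-number (CNV) records never enter the score; only SNVs and indels do.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from .models import (
    DataError,
    GIResult,
    PatientSampleSet,
    SharedMutation,
    VariantTable,
)
from .variant_io import normalize_alleles

#: leukocyte AF band retaining germline heterozygous variants (inclusive)
LEUKOCYTE_AF_BOUNDS = (0.2, 0.8)
#: quartile band around the theoretical het AF 0.5 (exclusive at the edges)
GI_BAND = (0.25, 0.75)
#: below this many shared mutations the score is reported indeterminate
DEFAULT_MIN_COMMON = 20


def filter_germline_hets(
    leukocyte: VariantTable,
    bounds: tuple[float, float] = LEUKOCYTE_AF_BOUNDS,
) -> VariantTable:
    """Retain the leukocyte SNV/indel records with AF inside ``bounds``.

    Variants with leukocyte AF below 0.2 or above 0.8 are removed so that
    only germline-derived common het mutations remain; the bounds themselves
    are retained.  Defined on the reference compartment only.
    """
    if leukocyte.compartment != "leukocyte":
        raise DataError(
            "germline het filter is defined on the leukocyte reference, "
            f"got compartment {leukocyte.compartment!r}"
        )
    lo, hi = bounds
    kept = [
        rec
        for rec in leukocyte.records
        if rec.kind in ("SNV", "indel")
        and rec.af is not None
        and lo <= rec.af <= hi
    ]
    return leukocyte.subset(kept)


def shared_mutations(
    leuk_filtered: VariantTable, assay: VariantTable
) -> list[SharedMutation]:
    """Variants present (by normalised key) in both reference and assay.

    Both tables must belong to the same patient.  CNV records never match.
    Keys are re-normalised here so tables produced outside the package's
    readers still compare canonically.
    """
    if leuk_filtered.patient_id != assay.patient_id:
        raise DataError(
            f"patient mismatch: {leuk_filtered.patient_id} vs {assay.patient_id}"
        )

    def norm_key(rec):
        pos, ref, alt = normalize_alleles(rec.pos, rec.ref, rec.alt)
        return (rec.chrom, pos, ref, alt)

    leuk_by_key = {
        norm_key(rec): rec
        for rec in leuk_filtered.records
        if rec.kind in ("SNV", "indel")
    }
    shared: list[SharedMutation] = []
    for rec in assay.records:
        if rec.kind not in ("SNV", "indel") or rec.af is None:
            continue
        key = norm_key(rec)
        leuk_rec = leuk_by_key.get(key)
        if leuk_rec is None:
            continue
        shared.append(
            SharedMutation(
                key=key,
                leukocyte_af=leuk_rec.af,
                sample_af=rec.af,
                alt_depth=rec.alt_depth,
                total_depth=rec.total_depth,
            )
        )
    return shared


def classify_gi_mutation(sample_af: float, band: tuple[float, float] = GI_BAND) -> bool:
    """True iff the assay AF lies outside the quartile band (strictly).

    An AF of exactly 0.25 or 0.75 is *not* a GI mutation.
    """
    if not (0.0 <= sample_af <= 1.0):
        raise DataError(f"allele fraction outside [0, 1]: {sample_af}")
    lo, hi = band
    return sample_af < lo or sample_af > hi


def compute_gi_score(
    shared: Iterable[SharedMutation],
    min_common: int = DEFAULT_MIN_COMMON,
    *,
    patient_id: str = "",
    sample_id: str = "",
    compartment: str = "",
    band: tuple[float, float] = GI_BAND,
) -> GIResult:
    """Score one (patient, compartment) from its shared-mutation list.

    score = n_gi / n_common.  When fewer than ``min_common`` mutations are
    shared the result is indeterminate with score None — a ratio of tiny
    counts is not a score of zero.
    """
    shared = list(shared)
    n_common = len(shared)
    n_gi = sum(classify_gi_mutation(m.sample_af, band) for m in shared)
    if n_common < min_common:
        result = GIResult(
            patient_id=patient_id,
            sample_id=sample_id,
            compartment=compartment,
            n_common=n_common,
            n_gi=n_gi,
            score=None,
            status="indeterminate",
        )
    else:
        result = GIResult(
            patient_id=patient_id,
            sample_id=sample_id,
            compartment=compartment,
            n_common=n_common,
            n_gi=n_gi,
            score=n_gi / n_common,
        )
    result.validate()
    return result


def score_sample(
    patient: PatientSampleSet,
    compartment: str,
    min_common: int = DEFAULT_MIN_COMMON,
    leukocyte_bounds: tuple[float, float] = LEUKOCYTE_AF_BOUNDS,
    band: tuple[float, float] = GI_BAND,
) -> Optional[GIResult]:
    """Full §-by-§ scoring of one assay compartment of one patient.

    Returns None when the patient has no sample for that compartment
    (scoring is skipped, not failed).
    """
    assay = getattr(patient, compartment, None)
    if assay is None:
        return None
    leuk = filter_germline_hets(patient.leukocyte, leukocyte_bounds)
    shared = shared_mutations(leuk, assay)
    return compute_gi_score(
        shared,
        min_common,
        patient_id=patient.patient_id,
        sample_id=assay.sample_id,
        compartment=compartment,
        band=band,
    )


def score_cohort(
    patients: Iterable[PatientSampleSet],
    compartments: tuple[str, ...] = ("csf", "plasma", "tissue"),
    min_common: int = DEFAULT_MIN_COMMON,
    leukocyte_bounds: tuple[float, float] = LEUKOCYTE_AF_BOUNDS,
    band: tuple[float, float] = GI_BAND,
) -> list[GIResult]:
    results: list[GIResult] = []
    for patient in patients:
        for comp in compartments:
            res = score_sample(patient, comp, min_common, leukocyte_bounds, band)
            if res is not None:
                results.append(res)
    return results


def results_frame(results: Iterable[GIResult]) -> pd.DataFrame:
    """Per-sample score table, one row per scored sample."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "sample_id": r.sample_id,
                "compartment": r.compartment,
                "n_common": r.n_common,
                "n_gi": r.n_gi,
                "score": r.score,
                "status": r.status,
                "cutoff_used": r.cutoff_used,
            }
            for r in results
        ]
    )
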