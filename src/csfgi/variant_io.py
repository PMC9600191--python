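"""Reading and writing variant tables, manifests and clinical tables.

Two on-disk representations are supported and round-trip through the same
in-memory model:

* VCF v4.2 (single-sample, GT/AD/DP in FORMAT; gene symbol, variant kind and
  copy number carried in INFO as GENE/VKIND/CN).  Parsed with cyvcf2.
* A TSV dialect with one header row and the columns
  ``chrom pos ref alt kind gene alt_depth total_depth af copy_number``.

All records are normalised on ingest: multi-allelic VCF rows are split into
one record per ALT, and indel alleles are trimmed to their minimal
representation (common suffix then common prefix) so that the same indel
written in different forms matches across compartments.

AF precedence: when both an AF value and read depths are present and
disagree by more than 0.01, the depths win and a warning is logged.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .genome import AUTOSOME_LENGTHS
from .models import (
    COMPARTMENTS,
    ClinicalRecord,
    ConfigError,
    DataError,
    PatientSampleSet,
    VariantRecord,
    VariantTable,
)

logger = logging.getLogger(__name__)

TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "kind",
    "gene",
    "alt_depth",
    "total_depth",
    "af",
    "copy_number",
]

CLINICAL_COLUMNS = [
    "patient_id",
    "sex",
    "age",
    "primary_tumor",
    "kps",
    "icp_kpa",
    "lp_shunt",
    "mfs_time",
    "mfs_event",
    "os_time",
    "os_event",
]


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal (trimmed) representation of an allele pair.

    Shared trailing bases are removed first, then shared leading bases
    (advancing the position), always keeping at least one base on each
    allele.  Symbolic ALTs (``<CNV>`` etc.) are returned unchanged.
    """
    if alt.startswith("<"):
        return pos, ref, alt
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def infer_kind(ref: str, alt: str) -> str:
    if alt.startswith("<"):
        return "CNV"
    return "SNV" if len(ref) == 1 and len(alt) == 1 else "indel"


def _make_record(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    kind: Optional[str],
    gene: Optional[str],
    alt_depth: Optional[int],
    total_depth: Optional[int],
    af: Optional[float],
    copy_number: Optional[float],
    context: str,
) -> Optional[VariantRecord]:
    """Build one normalised record, applying the AF-precedence rule.

    Returns None (with a warning) when a non-CNV record carries neither an
    AF nor usable depths.
    """
    pos, ref, alt = normalize_alleles(pos, ref, alt)
    kind = kind or infer_kind(ref, alt)
    if kind == "CNV":
        return VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, kind="CNV", gene=gene,
            copy_number=copy_number,
        )
    if alt_depth is not None and total_depth is not None and total_depth > 0:
        depth_af = alt_depth / total_depth
        if af is not None and abs(af - depth_af) > 0.01:
            logger.warning(
                "%s: AF %.4f disagrees with AD/DP %.4f at %s:%d; using depths",
                context, af, depth_af, chrom, pos,
            )
        af = depth_af
    elif af is None:
        logger.warning(
            "%s: record at %s:%d has neither AF nor depths; rejected",
            context, chrom, pos,
        )
        return None
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, kind=kind, gene=gene,
        alt_depth=alt_depth, total_depth=total_depth, af=af,
    )


# ---------------------------------------------------------------------------
# VCF

def _read_vcf(path: Path, context: str) -> list[VariantRecord]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise DataError(f"cannot parse VCF {path}: {exc}") from exc
    records: list[VariantRecord] = []
    try:
        for v in vcf:
            gene = v.INFO.get("GENE")
            vkind = v.INFO.get("VKIND")
            cn = v.INFO.get("CN")
            ad = v.format("AD")
            dp = v.format("DP")
            total = int(dp[0][0]) if dp is not None else None
            for i, alt in enumerate(v.ALT):
                alt_depth = None
                if ad is not None and len(ad[0]) > i + 1 and ad[0][i + 1] >= 0:
                    alt_depth = int(ad[0][i + 1])
                info_af = v.INFO.get("AF")
                if isinstance(info_af, tuple):
                    info_af = info_af[i]
                rec = _make_record(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    kind=vkind if len(v.ALT) == 1 else None,
                    gene=gene,
                    alt_depth=alt_depth,
                    total_depth=total,
                    af=float(info_af) if info_af is not None else None,
                    # CN is written with 6 significant digits; undo the
                    # float32 widening htslib applies to INFO floats
                    copy_number=float(f"{float(cn):.6g}") if cn is not None else None,
                    context=context,
                )
                if rec is not None:
                    records.append(rec)
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"malformed VCF body in {path}: {exc}") from exc
    return records


def _vcf_header(sample_id: str, contigs: Iterable[str]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=csfgi"]
    for chrom in contigs:
        length = AUTOSOME_LENGTHS.get(chrom, 300_000_000)
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=VKIND,Number=1,Type=String,Description="Variant kind">',
        '##INFO=<ID=CN,Number=1,Type=Float,Description="Observed copy number">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="ALT allele fraction">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id,
    ]
    return "\n".join(lines) + "\n"


def _write_vcf(table: VariantTable, path: Path) -> None:
    contigs: list[str] = []
    for rec in table.records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
    rows = []
    for rec in sorted(table.records, key=lambda r: (contigs.index(r.chrom), r.pos)):
        info = []
        if rec.gene:
            info.append(f"GENE={rec.gene}")
        info.append(f"VKIND={rec.kind}")
        if rec.kind == "CNV":
            info.append(f"CN={rec.copy_number:.6g}")
            rows.append(
                f"{rec.chrom}\t{rec.pos}\t.\tN\t<CNV>\t.\tPASS\t"
                f"{';'.join(info)}\tGT\t./."
            )
            continue
        if rec.af is not None:
            info.append(f"AF={rec.af!r}")
        if rec.alt_depth is not None and rec.total_depth is not None:
            ref_depth = rec.total_depth - rec.alt_depth
            sample = f"0/1:{ref_depth},{rec.alt_depth}:{rec.total_depth}"
            fmt = "GT:AD:DP"
        else:
            sample, fmt = "0/1", "GT"
        rows.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t"
            f"{';'.join(info)}\t{fmt}\t{sample}"
        )
    path.write_text(_vcf_header(table.sample_id, contigs) + "".join(r + "\n" for r in rows))


# ---------------------------------------------------------------------------
# TSV

def _read_tsv(path: Path, context: str) -> list[VariantRecord]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise DataError(f"cannot parse TSV {path}: {exc}") from exc
    missing = set(TSV_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise DataError(f"{path}: TSV missing required columns {sorted(missing)}")
    records: list[VariantRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            def get(col):
                val = row.get(col, "")
                return None if val in ("", None) else val

            rec = _make_record(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                kind=get("kind"),
                gene=get("gene"),
                alt_depth=int(get("alt_depth")) if get("alt_depth") else None,
                total_depth=int(get("total_depth")) if get("total_depth") else None,
                af=float(get("af")) if get("af") else None,
                copy_number=float(get("copy_number")) if get("copy_number") else None,
                context=context,
            )
        except (ValueError, KeyError) as exc:
            raise DataError(f"{path}: malformed row at line {line_no}: {exc}") from exc
        if rec is not None:
            records.append(rec)
    return records


def _write_tsv(table: VariantTable, path: Path) -> None:
    rows = []
    for rec in table.records:
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "kind": rec.kind,
                "gene": rec.gene if rec.gene is not None else "",
                "alt_depth": rec.alt_depth if rec.alt_depth is not None else "",
                "total_depth": rec.total_depth if rec.total_depth is not None else "",
                "af": repr(rec.af) if rec.af is not None else "",
                "copy_number": repr(rec.copy_number)
                if rec.copy_number is not None
                else "",
            }
        )
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Public API

def read_variant_table(
    path: str | Path,
    format: Optional[str] = None,
    *,
    sample_id: Optional[str] = None,
    patient_id: Optional[str] = None,
    compartment: str = "csf",
) -> VariantTable:
    """Read a variant table from VCF or TSV into the internal model.

    ``format`` is inferred from the file suffix when omitted.  Records are
    normalised (multi-allelic split, indel trimming) and validated; a
    duplicate normalised key raises a :class:`DataError` naming the key.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"variant table not found: {path}")
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format not in ("vcf", "tsv"):
        raise ConfigError(f"unknown variant table format {format!r} (expected vcf or tsv)")
    sample_id = sample_id or path.stem
    context = f"{path.name}"
    if format == "vcf":
        records = _read_vcf(path, context)
    else:
        records = _read_tsv(path, context)
    table = VariantTable(
        sample_id=sample_id,
        patient_id=patient_id or sample_id,
        compartment=compartment,
        records=records,
    )
    table.validate()
    return table


def write_variant_table(table: VariantTable, path: str | Path, format: Optional[str] = None) -> Path:
    """Write a table as VCF or TSV; the retained fields round-trip exactly."""
    path = Path(path)
    table.validate()
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "vcf":
        _write_vcf(table, path)
    elif format == "tsv":
        _write_tsv(table, path)
    else:
        raise ConfigError(f"unknown variant table format {format!r} (expected vcf or tsv)")
    return path


# ---------------------------------------------------------------------------
# Clinical table and manifest

def _to_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return bool(int(value))
    return str(value).strip().lower() in ("1", "true", "yes")


def read_clinical_table(path: str | Path) -> dict[str, ClinicalRecord]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"clinical table not found: {path}")
    df = pd.read_csv(path)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: clinical table missing columns {sorted(missing)}")
    out: dict[str, ClinicalRecord] = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        if pid in out:
            raise DataError(f"{path}: duplicate clinical row for patient {pid}")
        rec = ClinicalRecord(
            patient_id=pid,
            sex=str(row["sex"]),
            age=float(row["age"]),
            primary_tumor=str(row["primary_tumor"]),
            kps=int(row["kps"]),
            icp_kpa=float(row["icp_kpa"]),
            lp_shunt=_to_bool(row["lp_shunt"]),
            mfs_time=float(row["mfs_time"]),
            mfs_event=_to_bool(row["mfs_event"]),
            os_time=float(row["os_time"]),
            os_event=_to_bool(row["os_event"]),
        )
        rec.validate()
        out[pid] = rec
    return out


def write_clinical_table(records: Iterable[ClinicalRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        rows.append(
            {
                "patient_id": rec.patient_id,
                "sex": rec.sex,
                "age": repr(rec.age),
                "primary_tumor": rec.primary_tumor,
                "kps": rec.kps,
                "icp_kpa": repr(rec.icp_kpa),
                "lp_shunt": int(rec.lp_shunt),
                "mfs_time": repr(rec.mfs_time),
                "mfs_event": int(rec.mfs_event),
                "os_time": repr(rec.os_time),
                "os_event": int(rec.os_event),
            }
        )
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)
    return path


def load_manifest(
    manifest_path: str | Path, clinical_path: Optional[str | Path] = None
) -> list[PatientSampleSet]:
    """Assemble patient sample sets from a manifest CSV.

    The manifest has columns ``patient_id, sample_id, compartment, path``;
    paths are resolved relative to the manifest's directory.  Patients
    without a leukocyte table are excluded with a logged warning; a
    duplicate (patient, compartment) pair is an error.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DataError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path, dtype=str)
    required = {"patient_id", "sample_id", "compartment", "path"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{manifest_path}: manifest missing columns {sorted(missing)}")

    clinical = read_clinical_table(clinical_path) if clinical_path else {}

    tables: dict[str, dict[str, VariantTable]] = {}
    for idx, row in df.iterrows():
        pid, comp = str(row["patient_id"]), str(row["compartment"])
        if comp not in COMPARTMENTS:
            raise DataError(
                f"{manifest_path}: row {idx + 2}: unknown compartment {comp!r}"
            )
        if comp in tables.get(pid, {}):
            raise DataError(
                f"{manifest_path}: duplicate (patient, compartment) pair "
                f"({pid}, {comp})"
            )
        table_path = Path(row["path"])
        if not table_path.is_absolute():
            table_path = manifest_path.parent / table_path
        if not table_path.exists():
            raise DataError(
                f"{manifest_path}: row {idx + 2} points to missing file {table_path}"
            )
        table = read_variant_table(
            table_path,
            sample_id=str(row["sample_id"]),
            patient_id=pid,
            compartment=comp,
        )
        tables.setdefault(pid, {})[comp] = table

    patients: list[PatientSampleSet] = []
    for pid, comps in tables.items():
        if "leukocyte" not in comps:
            logger.warning("patient %s has no leukocyte table; excluded", pid)
            continue
        pset = PatientSampleSet(
            patient_id=pid,
            leukocyte=comps["leukocyte"],
            csf=comps.get("csf"),
            plasma=comps.get("plasma"),
            tissue=comps.get("tissue"),
            clinical=clinical.get(pid),
        )
        pset.validate()
        patients.append(pset)
    return patients
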