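"""Copy-number validation from binned read counts.

Low-depth whole-genome sequencing provides an orthogonal check on the
AF-based GI score: read counts in fixed genome bins are normalised to
log2 ratios against the autosomal median, merged into segments, and the
altered genome fraction (AGF) — the fraction of genome length in segments
whose |mean log2 ratio| exceeds the gain/loss threshold — is compared with
the score-based GI/GS call.

Normalisation is by the median autosomal bin count only (no GC or
mappability correction).  Segmentation is a deliberately minimal greedy
mean-merge: adjacent bins join the current segment while they stay within
``merge_tol`` of its running mean.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genome import is_autosome
from .models import BinTrack, CNVCallSummary, DataError, GIResult

#: |log2 ratio| above which a segment counts as gained/lost
DEFAULT_GAIN_LOSS_THRESHOLD = 0.2
#: AGF at or above which the copy-number profile is called genome-unstable
DEFAULT_AGF_THRESHOLD = 0.10
#: running-mean tolerance for merging adjacent bins
DEFAULT_MERGE_TOL = 0.1


def compute_log2_ratios(track: BinTrack) -> BinTrack:
    """Normalise raw bin counts to log2 ratios against the autosomal median.

    Bins with zero counts are flagged missing (NaN ratio) and ignored by
    downstream segmentation.  Scaling every count by a constant leaves the
    ratios unchanged.
    """
    track.validate()
    bins = track.bins.copy()
    counts = bins["raw_count"].to_numpy(dtype=float)
    auto = bins["chrom"].map(is_autosome).to_numpy(dtype=bool)
    nonzero = counts > 0
    if not (auto & nonzero).any():
        raise DataError(f"{track.sample_id}: no non-zero autosomal bins to normalise")
    median = float(np.median(counts[auto & nonzero]))
    log2 = np.full(len(counts), np.nan)
    log2[nonzero] = np.log2(counts[nonzero] / median)
    bins["log2_ratio"] = log2
    return BinTrack(sample_id=track.sample_id, bins=bins, bin_size=track.bin_size)


def segment_track(
    track: BinTrack,
    merge_tol: float = DEFAULT_MERGE_TOL,
    gain_loss_threshold: float = DEFAULT_GAIN_LOSS_THRESHOLD,
) -> CNVCallSummary:
    """Greedy mean-merge segmentation and AGF summary of a normalised track.

    Per chromosome, bins are scanned in order; a bin extends the open
    segment while its log2 ratio differs from the segment's running mean by
    less than ``merge_tol``, otherwise a new segment opens.  AGF is the
    length fraction of segments with |mean log2| > ``gain_loss_threshold``.
    """
    if "log2_ratio" not in track.bins.columns:
        raise DataError("track is not normalised; run compute_log2_ratios first")
    seg_rows = []
    for chrom, group in track.bins.groupby("chrom", sort=False):
        group = group.sort_values("start")
        vals = group["log2_ratio"].to_numpy()
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        open_idx: Optional[int] = None
        acc_sum, acc_n = 0.0, 0
        for i in range(len(group)):
            if np.isnan(vals[i]):
                continue
            if open_idx is None:
                open_idx, acc_sum, acc_n = i, vals[i], 1
                continue
            mean = acc_sum / acc_n
            if abs(vals[i] - mean) < merge_tol:
                acc_sum += vals[i]
                acc_n += 1
            else:
                seg_rows.append(
                    (chrom, int(starts[open_idx]), int(ends[i - 1]), acc_n, acc_sum / acc_n)
                )
                open_idx, acc_sum, acc_n = i, vals[i], 1
        if open_idx is not None:
            seg_rows.append(
                (chrom, int(starts[open_idx]), int(ends[len(group) - 1]), acc_n, acc_sum / acc_n)
            )
    segments = pd.DataFrame(
        seg_rows, columns=["chrom", "start", "end", "n_bins", "mean_log2"]
    )
    total = float((segments["end"] - segments["start"]).sum()) if len(segments) else 0.0
    if total > 0:
        altered = segments.loc[
            segments["mean_log2"].abs() > gain_loss_threshold, ["start", "end"]
        ]
        agf = float((altered["end"] - altered["start"]).sum()) / total
    else:
        agf = 0.0
    return CNVCallSummary(
        sample_id=track.sample_id,
        segments=segments,
        altered_genome_fraction=agf,
    )


def gi_concordance(
    summary: CNVCallSummary,
    result: GIResult,
    agf_threshold: float = DEFAULT_AGF_THRESHOLD,
) -> Optional[bool]:
    """Does the copy-number AGF call agree with the score-based status?

    Returns True iff (AGF >= threshold) matches (status == GI); None when
    the score-based status is indeterminate or unset.
    """
    if summary.sample_id != result.sample_id:
        raise DataError(
            f"sample mismatch: {summary.sample_id} vs {result.sample_id}"
        )
    if result.status in (None, "indeterminate"):
        return None
    return (summary.altered_genome_fraction >= agf_threshold) == (
        result.status == "GI"
    )


# ---------------------------------------------------------------------------
# BED-like TSV I/O for bin tracks

def read_bin_track(path: str | Path, sample_id: Optional[str] = None) -> BinTrack:
    path = Path(path)
    if not path.exists():
        raise DataError(f"bin track not found: {path}")
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "raw_count"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: bin track missing columns {sorted(required - set(df.columns))}")
    sizes = (df["end"] - df["start"]).to_numpy()
    bin_size = int(np.median(sizes)) if len(sizes) else 0
    track = BinTrack(sample_id=sample_id or path.stem, bins=df, bin_size=bin_size)
    track.validate()
    return track


def write_bin_track(track: BinTrack, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["chrom", "start", "end", "raw_count"]
    if "log2_ratio" in track.bins.columns:
        cols.append("log2_ratio")
    track.bins[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
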