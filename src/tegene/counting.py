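"""Read counting over TE instances from coordinate-sorted BAM files.

A read is attributed to an instance only when its aligned reference span is
fully contained in the instance interval ("100% overlap").  Containment is
judged on the reference span of the alignment: soft-clipped bases are
outside the span, deletions and introns are inside it (CIGAR reference
length).  Each mate of a pair counts independently, and a read contained in
several overlapping instances counts toward all of them.

High MAPQ thresholds select uniquely mapped reads; pass ``min_mapq=60`` to
emulate a ``samtools view -bq 60`` pre-filter instead of filtering the BAM
up front.  The default is 0 so already-filtered BAMs are not double-filtered.
"""

from __future__ import annotations

import logging
import os
import warnings
from typing import Sequence

import pandas as pd
import pysam

from .proximity import TEGeneLink
from .repeats import RepeatInstance

log = logging.getLogger(__name__)

__all__ = ["count_reads_in_instances", "summarize_te_counts"]


def _read_passes(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.mapping_quality < min_mapq
    )


def count_reads_in_instances(
    bam_paths: Sequence,
    instances: Sequence[RepeatInstance],
    min_mapq: int = 0,
    sample_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Count fully-contained reads per TE instance per sample.

    Parameters
    ----------
    bam_paths
        Coordinate-sorted, indexed BAM files, one per sample, in the user's
        sample order.
    instances
        TE instances to count over.
    min_mapq
        Minimum mapping quality; 60 restricts to uniquely mapped reads for
        typical aligners.
    sample_names
        Column labels; defaults to BAM basenames without extension.

    Returns
    -------
    DataFrame of non-negative integer counts, rows indexed by
    ``instance_id``, columns in the given sample order.

    Raises
    ------
    FileNotFoundError
        If a BAM has no index.
    """
    if sample_names is None:
        sample_names = [os.path.basename(str(p)).removesuffix(".bam") for p in bam_paths]
    if len(sample_names) != len(bam_paths):
        raise ValueError("sample_names and bam_paths differ in length")

    ids = [t.instance_id for t in instances]
    counts = pd.DataFrame(0, index=pd.Index(ids, name="instance_id"), columns=list(sample_names))

    for path, sample in zip(bam_paths, sample_names):
        with pysam.AlignmentFile(str(path), "rb") as bam:
            try:
                has_index = bam.check_index()
            except (ValueError, AttributeError):
                has_index = False
            if not has_index:
                raise FileNotFoundError(f"BAM index missing for {path} (run samtools index)")
            refs = set(bam.references)
            missing = {t.chrom for t in instances} - refs
            if missing:
                warnings.warn(
                    f"{path}: chromosomes {sorted(missing)} absent from BAM header; "
                    "their instances get zero counts"
                )
            for t in instances:
                if t.chrom not in refs:
                    continue
                n = 0
                for read in bam.fetch(t.chrom, t.start, t.end):
                    if not _read_passes(read, min_mapq):
                        continue
                    if read.reference_start >= t.start and read.reference_end <= t.end:
                        n += 1
                counts.at[t.instance_id, sample] = n
    return counts


def summarize_te_counts(
    links: Sequence[TEGeneLink],
    instance_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate instance counts into per-(gene, repeat_name) totals.

    Every row of the result is the per-sample sum over the link's member
    instances; an instance shared by several genes contributes to each of
    their rows.  Rows are keyed ``"<gene_id>|<repeat_name>"`` and carry the
    pair in a two-level index-free form usable as merged-matrix keys.

    Raises
    ------
    KeyError
        If a link references an instance id absent from ``instance_counts``.
    """
    rows = {}
    for link in links:
        for iid in link.instance_ids:
            if iid not in instance_counts.index:
                raise KeyError(f"instance {iid!r} not present in the instance count matrix")
        rows[link.key] = instance_counts.loc[list(link.instance_ids)].sum(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "te_key"
    out.columns = instance_counts.columns
    return out.astype(int)
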