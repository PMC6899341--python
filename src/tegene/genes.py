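"""Gene interval resolution from local GTF/BED annotation.

Genes named in the user's count matrix are looked up in a local annotation
file rather than a live Ensembl query, keeping runs hermetic.  GTF
coordinates (1-based inclusive) are converted to the package-wide 0-based
half-open convention; the TSS is the strand-aware 5' end.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

log = logging.getLogger(__name__)

__all__ = ["GeneInterval", "load_gene_intervals", "write_intervals_tsv", "read_intervals_tsv"]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

_ID_KINDS = ("symbol", "ensembl_gene", "ensembl_transcript")


@dataclass(frozen=True)
class GeneInterval:
    """Genomic span of one gene (or transcript), with its TSS.

    ``tss`` is the 0-based position of the 5' end: ``start`` on the plus
    strand, ``end - 1`` on the minus strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end}) for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


def _strip_version(identifier: str) -> str:
    # ENSG00000123456.7 -> ENSG00000123456
    return re.sub(r"\.\d+$", "", identifier)


def _iter_gtf_features(path, feature: str, attr_key: str):
    with open(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != feature:
                continue
            attrs = dict(_ATTR_RE.findall(fields[8]))
            name = attrs.get(attr_key)
            if name is None:
                continue
            yield name, fields[0], int(fields[3]) - 1, int(fields[4]), fields[6]


def _iter_bed(path):
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: need BED6 (name=gene id)")
            yield fields[3], fields[0], int(fields[1]), int(fields[2]), fields[5]


def load_gene_intervals(
    annotation_path,
    requested_ids: Sequence[str],
    id_kind: str = "symbol",
) -> tuple[list[GeneInterval], list[str]]:
    """Resolve genomic intervals for the requested gene identifiers.

    Parameters
    ----------
    annotation_path
        A GTF file (``gene`` feature lines are used, or ``transcript`` lines
        when ``id_kind='ensembl_transcript'``) or a BED6 file (detected by a
        ``.bed`` suffix; the name column carries the identifier).
    requested_ids
        Identifiers as they appear in the count-matrix rows: official gene
        symbols, Ensembl gene IDs or Ensembl transcript IDs per ``id_kind``.
        Version suffixes on Ensembl IDs are ignored when matching.
    id_kind
        One of ``symbol``, ``ensembl_gene``, ``ensembl_transcript``.

    Returns
    -------
    (matched, unmatched)
        ``matched`` follows the order of ``requested_ids``; each identifier
        maps to a single interval.  When the annotation holds several entries
        for one identifier the longest span wins (and the conflict is
        logged).  ``unmatched`` lists identifiers with no annotation entry.

    Raises
    ------
    ValueError
        If no identifier matches at all — usually a wrong ``id_kind`` or an
        annotation from a different genome build.
    """
    if id_kind not in _ID_KINDS:
        raise ValueError(f"id_kind must be one of {_ID_KINDS}, got {id_kind!r}")
    if not requested_ids:
        raise ValueError("requested_ids is empty")

    is_ensembl = id_kind.startswith("ensembl")
    path_str = str(annotation_path)
    if path_str.endswith(".bed") or path_str.endswith(".bed.gz"):
        entries = _iter_bed(annotation_path)
    else:
        feature = "transcript" if id_kind == "ensembl_transcript" else "gene"
        attr_key = {
            "symbol": "gene_name",
            "ensembl_gene": "gene_id",
            "ensembl_transcript": "transcript_id",
        }[id_kind]
        entries = _iter_gtf_features(annotation_path, feature, attr_key)

    best: dict[str, GeneInterval] = {}
    for name, chrom, start, end, strand in entries:
        key = _strip_version(name) if is_ensembl else name
        iv = GeneInterval(gene_id=key, chrom=chrom, start=start, end=end, strand=strand)
        prev = best.get(key)
        if prev is None:
            best[key] = iv
        elif iv.length > prev.length:
            log.warning(
                "identifier %s maps to multiple annotation entries; keeping longest span", key
            )
            best[key] = iv
        else:
            log.warning(
                "identifier %s maps to multiple annotation entries; keeping longest span", key
            )

    matched: list[GeneInterval] = []
    unmatched: list[str] = []
    for rid in requested_ids:
        key = _strip_version(rid) if is_ensembl else rid
        iv = best.get(key)
        if iv is None:
            unmatched.append(rid)
        else:
            # report under the identifier the caller used, so count-matrix
            # rows and intervals share keys even with version suffixes
            matched.append(
                GeneInterval(rid, iv.chrom, iv.start, iv.end, iv.strand)
            )
    if not matched:
        raise ValueError(
            f"none of the {len(requested_ids)} requested identifiers matched "
            f"{annotation_path} with id_kind={id_kind!r}; check id_kind and genome build"
        )
    return matched, unmatched


def write_intervals_tsv(intervals: Sequence[GeneInterval], path) -> None:
    with open(path, "wt") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\ttss\n")
        for iv in intervals:
            fh.write(f"{iv.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{iv.tss}\n")


def read_intervals_tsv(path) -> list[GeneInterval]:
    intervals = []
    with open(path, "rt") as fh:
        header = fh.readline()
        if not header.startswith("gene_id\t"):
            raise ValueError(f"{path}: not an interval table")
        for line in fh:
            gene_id, chrom, start, end, strand, _tss = line.rstrip("\n").split("\t")
            intervals.append(GeneInterval(gene_id, chrom, int(start), int(end), strand))
    return intervals
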