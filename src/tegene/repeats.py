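"""RepeatMasker annotation parsing.

RepeatMasker genomic ``.out`` files are whitespace-columned tables with a
three-line header, 1-based inclusive coordinates and ``C`` marking the
complement strand.  This module normalises them into :class:`RepeatInstance`
records using 0-based half-open coordinates, the convention used everywhere
inside this package; coordinate conversion happens only here and in the
BED writers/readers.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "RepeatInstance",
    "parse_repeatmasker",
    "write_bed6",
    "read_bed6",
]


@dataclass(frozen=True)
class RepeatInstance:
    """One genomic copy of a repeat/transposable element.

    Coordinates are 0-based half-open.  ``repeat_class`` and ``repeat_family``
    come from splitting RepeatMasker's ``class/family`` column at the first
    slash; when there is no slash the family repeats the class so neither
    field is ever empty.
    """

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_class: str
    repeat_family: str
    sw_score: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.repeat_name}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def instance_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.repeat_name}"


def _open_text(path) -> io.TextIOBase:
    # gzip detected by magic bytes, not extension: RepeatMasker distributes .out.gz
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def parse_repeatmasker(
    path,
    keep_classes: Iterable[str] | None = None,
) -> list[RepeatInstance]:
    """Parse a RepeatMasker genomic ``.out`` file into repeat instances.

    Parameters
    ----------
    path
        Path to a ``.out`` file (plain or gzip; detected by magic bytes).
        The standard three header lines are skipped.
    keep_classes
        Optional set of top-level repeat classes (e.g. ``{"LINE", "SINE"}``).
        When given, only instances whose ``repeat_class`` is in the set are
        returned; equivalent to parsing everything and filtering afterwards.

    Returns
    -------
    list of RepeatInstance sorted by (chrom, start).  An empty file body
    (header only) yields an empty list.

    Raises
    ------
    ValueError
        On a malformed data line, naming its 1-based line number.
    """
    keep = set(keep_classes) if keep_classes is not None else None
    records: list[RepeatInstance] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3:  # "SW score  perc ..." header + blank line
                continue
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 15:
                raise ValueError(
                    f"{path}: malformed RepeatMasker line {lineno}: "
                    f"expected >= 15 fields, got {len(fields)}"
                )
            try:
                sw_score = int(fields[0])
                chrom = fields[4]
                begin_1based = int(fields[5])
                end_1based = int(fields[6])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed RepeatMasker line {lineno}: {exc}"
                ) from None
            strand = "-" if fields[8] == "C" else fields[8]
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}: malformed RepeatMasker line {lineno}: "
                    f"strand token {fields[8]!r}"
                )
            # trailing "*" marks an instance overshadowed by a higher-scoring
            # overlap; such lines are kept, the flag stripped
            repeat_name = fields[9].rstrip("*")
            class_family = fields[10]
            if "/" in class_family:
                repeat_class, repeat_family = class_family.split("/", 1)
            else:
                repeat_class = repeat_family = class_family
            if keep is not None and repeat_class not in keep:
                continue
            records.append(
                RepeatInstance(
                    chrom=chrom,
                    start=begin_1based - 1,
                    end=end_1based,
                    strand=strand,
                    repeat_name=repeat_name,
                    repeat_class=repeat_class,
                    repeat_family=repeat_family,
                    sw_score=sw_score,
                )
            )
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.repeat_name))
    ids = [r.instance_id for r in records]
    if len(set(ids)) != len(ids):
        log.warning("duplicate instance ids after parsing %s", path)
    return records


def write_bed6(records: Sequence[RepeatInstance], path) -> None:
    """Write instances as BED6: chrom, start, end, name, sw_score, strand."""
    with open(path, "wt") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.repeat_name}\t{r.sw_score}\t{r.strand}\n"
            )


def read_bed6(path) -> list[RepeatInstance]:
    """Read a BED6 file written by :func:`write_bed6`.

    Class/family information is not representable in BED6; both are set to
    the repeat name's value placeholder ``"."`` is avoided by reusing the name.
    """
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 BED columns")
            chrom, start, end, name, score, strand = fields[:6]
            records.append(
                RepeatInstance(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    repeat_name=name,
                    repeat_class=name,
                    repeat_family=name,
                    sw_score=int(float(score)),
                )
            )
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.repeat_name))
    return records
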