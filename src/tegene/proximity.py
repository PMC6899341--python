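"""Strand-aware linking of TE instances to nearby genes.

The anchor points are the gene's TSS and the TE's annotated start (its lower
genomic coordinate).  The signed distance of a TE at start ``s`` from a gene
is measured in the gene's upstream direction:

    d = tss - s   on the plus strand
    d = s - tss   on the minus strand

A positive ``distance`` window keeps TEs with ``0 < d <= distance`` (strictly
upstream, inclusive at the far boundary); a negative window keeps
``-|distance| <= d < 0`` (downstream).  A TE whose start coincides with the
TSS or lies downstream of it is never "upstream".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genes import GeneInterval
from .repeats import RepeatInstance

log = logging.getLogger(__name__)

__all__ = ["TEGeneLink", "find_proximal_tes", "write_links_tsv", "read_links_tsv"]

#: separator used to build merged-matrix row keys "<gene_id>|<repeat_name>"
TE_KEY_SEP = "|"


@dataclass(frozen=True)
class TEGeneLink:
    """All instances of one repeat subfamily linked to one gene.

    ``distances`` are signed upstream-direction distances (bp) from the gene
    TSS, aligned with ``instance_ids``.
    """

    gene_id: str
    repeat_name: str
    instance_ids: tuple[str, ...]
    distances: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.instance_ids:
            raise ValueError("a link must have at least one instance")
        if len(self.instance_ids) != len(self.distances):
            raise ValueError("instance_ids and distances differ in length")

    @property
    def key(self) -> str:
        return f"{self.gene_id}{TE_KEY_SEP}{self.repeat_name}"


def _te_filter_pred(te_filter: Iterable[str] | None):
    if te_filter is None:
        return lambda t: True
    wanted = set(te_filter)
    return lambda t: (
        t.repeat_class in wanted or t.repeat_family in wanted or t.repeat_name in wanted
    )


def find_proximal_tes(
    genes: Sequence[GeneInterval],
    tes: Sequence[RepeatInstance],
    distance: int = 5000,
    strand_match: bool = False,
    te_filter: Iterable[str] | None = None,
) -> list[TEGeneLink]:
    """Link TE instances falling in each gene's upstream (or downstream) window.

    Parameters
    ----------
    genes, tes
        Gene intervals and repeat instances on the same assembly naming.
    distance
        Signed window size in bp.  Positive selects the upstream window
        ``0 < d <= distance``; negative selects the downstream window
        ``-|distance| <= d < 0``.  The default 5000 matches the common
        5 kb-upstream promoter-proximal analysis window.
    strand_match
        Require the TE to lie on the gene's strand.
    te_filter
        Optional set of repeat class, family or subfamily names; an instance
        passes if any of its three labels is in the set.

    Returns
    -------
    One :class:`TEGeneLink` per (gene, repeat_name) pair with at least one
    instance in the window.  Genes keep their input order; within a gene,
    links are ordered by repeat_name.
    """
    if distance == 0:
        raise ValueError("distance must be non-zero (positive=upstream, negative=downstream)")

    pred = _te_filter_pred(te_filter)
    kept = [t for t in tes if pred(t)]

    by_chrom: dict[str, tuple[np.ndarray, list[RepeatInstance]]] = {}
    for chrom in {t.chrom for t in kept}:
        sub = sorted((t for t in kept if t.chrom == chrom), key=lambda t: t.start)
        by_chrom[chrom] = (np.array([t.start for t in sub], dtype=np.int64), sub)

    links: list[TEGeneLink] = []
    width = abs(distance)
    for g in genes:
        if g.chrom not in by_chrom:
            continue
        starts, sub = by_chrom[g.chrom]
        # translate the d-window into an interval of TE start coordinates
        if distance > 0:  # upstream: 0 < d <= width
            if g.strand == "+":
                lo, hi = g.tss - width, g.tss - 1  # s in [tss-width, tss)
            else:
                lo, hi = g.tss + 1, g.tss + width  # s in (tss, tss+width]
        else:  # downstream: -width <= d < 0
            if g.strand == "+":
                lo, hi = g.tss + 1, g.tss + width
            else:
                lo, hi = g.tss - width, g.tss - 1
        i0 = int(np.searchsorted(starts, lo, side="left"))
        i1 = int(np.searchsorted(starts, hi, side="right"))
        grouped: dict[str, list[tuple[str, int]]] = {}
        for t in sub[i0:i1]:
            if strand_match and t.strand != g.strand:
                continue
            d = (g.tss - t.start) if g.strand == "+" else (t.start - g.tss)
            grouped.setdefault(t.repeat_name, []).append((t.instance_id, d))
        for name in sorted(grouped):
            members = grouped[name]
            links.append(
                TEGeneLink(
                    gene_id=g.gene_id,
                    repeat_name=name,
                    instance_ids=tuple(i for i, _ in members),
                    distances=tuple(d for _, d in members),
                )
            )
    if not links:
        log.warning("no TE-gene links found (distance=%d, strand_match=%s)", distance, strand_match)
    return links


def write_links_tsv(links: Sequence[TEGeneLink], tes: Sequence[RepeatInstance], path) -> None:
    """Write one row per linked instance: gene, repeat, location, distance."""
    by_id = {t.instance_id: t for t in tes}
    with open(path, "wt") as fh:
        fh.write("gene_id\trepeat_name\tchrom\tte_start\tte_end\tte_strand\tdistance\n")
        for link in links:
            for iid, d in zip(link.instance_ids, link.distances):
                t = by_id[iid]
                fh.write(
                    f"{link.gene_id}\t{link.repeat_name}\t{t.chrom}\t{t.start}\t"
                    f"{t.end}\t{t.strand}\t{d}\n"
                )


def read_links_tsv(path) -> list[TEGeneLink]:
    rows: dict[tuple[str, str], list[tuple[str, int]]] = {}
    order: list[tuple[str, str]] = []
    with open(path, "rt") as fh:
        header = fh.readline()
        if not header.startswith("gene_id\trepeat_name"):
            raise ValueError(f"{path}: not a links table")
        for line in fh:
            gene_id, name, chrom, s, e, _strand, d = line.rstrip("\n").split("\t")
            key = (gene_id, name)
            if key not in rows:
                rows[key] = []
                order.append(key)
            rows[key].append((f"{chrom}:{s}-{e}:{name}", int(d)))
    return [
        TEGeneLink(g, n, tuple(i for i, _ in rows[(g, n)]), tuple(d for _, d in rows[(g, n)]))
        for g, n in order
    ]
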