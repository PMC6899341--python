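"""Synthetic fixture generation with known ground truth.

Everything the pipeline consumes can be generated here: a RepeatMasker
``.out`` annotation, a GTF of gene models, sorted+indexed BAMs whose
per-instance read counts are known by construction, and count matrices
drawn from the forward model

    gene log2-CPM = b0 + sum_k beta_k * (TE_k log2-CPM) + covariates + N(0, noise_sd^2)

with counts drawn negative-binomially around the target CPM
(variance = mu + mu^2 * dispersion, the mean/dispersion convention).

Defaults mirror a paired-design bulk RNA-seq study: 44 samples = 22
patients x (normal, tumour) tissue, ~2e6 counted reads per sample.
All generators are pure functions of (config, seed): rerunning with the
same config reproduces byte-identical data files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .genes import GeneInterval
from .model import build_design, fit_gene_lm, ModelSpec
from .proximity import TE_KEY_SEP, TEGeneLink, find_proximal_tes
from .repeats import RepeatInstance

__all__ = [
    "SimulationConfig",
    "make_full_fixture",
    "make_annotation_fixture",
    "make_alignment_fixture",
    "simulate_expression",
    "null_te_term_pvalues",
]

# small realistic catalogue: (subfamily, class/family) across the four TE classes
_REPEAT_CATALOG = [
    ("L2c", "LINE/L2"),
    ("AluY", "SINE/Alu"),
    ("MLT1D", "LTR/ERVL-MaLR"),
    ("MER5B", "DNA/hAT-Charlie"),
    ("L1MB7", "LINE/L1"),
    ("MIR3", "SINE/MIR"),
]

#: structured upstream offsets planted for every gene (bp from the TSS in the
#: gene's upstream direction): one inside the gene body, two inside a 5 kb
#: window, one exactly on its boundary, one just outside.
_PLANT_OFFSETS = (-100, 1000, 4000, 5000, 6000)

_GENE_BODY = 2000
_TSS_MARGIN = 10000  # distance from slot start to the TSS
_SLOT_MIN = _TSS_MARGIN + _GENE_BODY + 4000


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for all generators.

    ``planted_effects`` lists (gene_id, repeat_name, beta) triples; every
    other gene-TE term has a true coefficient of zero.  ``reads_per_instance``
    is either one integer for all instances or a map instance_id -> reads.
    """

    seed: int = 0
    n_genes: int = 12
    n_te_instances: int = 60
    genome_length: int = 1_000_000
    n_samples: int = 44
    planted_effects: tuple[tuple[str, str, float], ...] = ()
    nb_dispersion: float = 0.05
    baseline_logcpm_range: tuple[float, float] = (3.0, 7.0)
    noise_sd: float = 0.5
    reads_per_instance: int = 30
    lib_size: int = 2_000_000
    read_length: int = 75
    chrom: str = "chrSim"


def _gene_id(i: int) -> str:
    return f"GENE{i + 1:04d}"


def make_annotation_fixture(cfg: SimulationConfig, out_dir):
    """Write a RepeatMasker ``.out`` and a GTF with a known gene/TE layout.

    Genes are placed in non-overlapping slots on alternating strands; for
    each gene, TE instances are planted at the upstream offsets in
    ``_PLANT_OFFSETS`` with a distinct repeat subfamily per offset, plus
    random filler instances up to ``n_te_instances``.

    Returns
    -------
    dict with keys ``rm_path``, ``gtf_path``, ``genes`` (GeneInterval list),
    ``instances`` (RepeatInstance list) and ``truth`` — a DataFrame of every
    (gene, instance) pair within 20 kb, with the signed upstream distance so
    the expected links for any window are known by construction.
    """
    slot = cfg.genome_length // cfg.n_genes
    if slot < _SLOT_MIN:
        raise ValueError(
            f"layout overflow: genome_length={cfg.genome_length} too small for "
            f"{cfg.n_genes} genes (need >= {cfg.n_genes * _SLOT_MIN})"
        )
    rng = np.random.default_rng([cfg.seed, 1])
    genes: list[GeneInterval] = []
    for i in range(cfg.n_genes):
        strand = "+" if i % 2 == 0 else "-"
        tss = i * slot + _TSS_MARGIN
        if strand == "+":
            start, end = tss, tss + _GENE_BODY
        else:
            start, end = tss - _GENE_BODY + 1, tss + 1
        genes.append(GeneInterval(_gene_id(i), cfg.chrom, start, end, strand))

    instances: list[RepeatInstance] = []
    for i, g in enumerate(genes):
        for j, off in enumerate(_PLANT_OFFSETS):
            name, classfam = _REPEAT_CATALOG[j % len(_REPEAT_CATALOG)]
            length = int(rng.integers(150, 400))
            s = g.tss - off if g.strand == "+" else g.tss + off
            if g.strand == "-":
                s -= 0  # anchor stays the lower coordinate
            if s < 0 or s + length > cfg.genome_length:
                raise ValueError("layout overflow: planted TE outside the genome")
            cls, fam = classfam.split("/")
            instances.append(
                RepeatInstance(
                    chrom=cfg.chrom,
                    start=int(s),
                    end=int(s + length),
                    strand=str(rng.choice(["+", "-"])),
                    repeat_name=name,
                    repeat_class=cls,
                    repeat_family=fam,
                    sw_score=int(rng.integers(200, 5000)),
                )
            )
    n_extra = max(0, cfg.n_te_instances - len(instances))
    for _ in range(n_extra):
        name, classfam = _REPEAT_CATALOG[int(rng.integers(len(_REPEAT_CATALOG)))]
        cls, fam = classfam.split("/")
        length = int(rng.integers(150, 400))
        s = int(rng.integers(0, cfg.genome_length - length))
        instances.append(
            RepeatInstance(
                chrom=cfg.chrom,
                start=s,
                end=s + length,
                strand=str(rng.choice(["+", "-"])),
                repeat_name=name,
                repeat_class=cls,
                repeat_family=fam,
                sw_score=int(rng.integers(200, 5000)),
            )
        )
    # drop accidental duplicate ids from random placement
    seen: set[str] = set()
    uniq = []
    for t in instances:
        if t.instance_id not in seen:
            seen.add(t.instance_id)
            uniq.append(t)
    instances = sorted(uniq, key=lambda t: (t.chrom, t.start, t.end))

    rows = []
    for g in genes:
        for t in instances:
            if t.chrom != g.chrom:
                continue
            d = (g.tss - t.start) if g.strand == "+" else (t.start - g.tss)
            if abs(d) <= 20000:
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "instance_id": t.instance_id,
                        "repeat_name": t.repeat_name,
                        "distance": d,
                    }
                )
    truth = pd.DataFrame(rows, columns=["gene_id", "instance_id", "repeat_name", "distance"])

    os.makedirs(out_dir, exist_ok=True)
    rm_path = os.path.join(out_dir, "repeats.out")
    _write_repeatmasker(instances, rm_path)
    gtf_path = os.path.join(out_dir, "genes.gtf")
    _write_gtf(genes, gtf_path)
    truth.to_csv(os.path.join(out_dir, "truth_layout.tsv"), sep="\t", index=False)
    return {
        "rm_path": rm_path,
        "gtf_path": gtf_path,
        "genes": genes,
        "instances": instances,
        "truth": truth,
    }


def _write_repeatmasker(instances: Sequence[RepeatInstance], path) -> None:
    header = (
        "   SW   perc perc perc  query     position in query            matching"
        "  repeat           position in repeat\n"
        "score   div. del. ins.  sequence  begin end          (left)    repeat"
        "    class/family      begin  end    (left)   ID\n"
        "\n"
    )
    with open(path, "wt") as fh:
        fh.write(header)
        for i, t in enumerate(instances, start=1):
            strand = "+" if t.strand == "+" else "C"
            classfam = (
                t.repeat_class
                if t.repeat_class == t.repeat_family
                else f"{t.repeat_class}/{t.repeat_family}"
            )
            star = " *" if i % 7 == 0 else ""  # exercise the overlap flag
            fh.write(
                f"{t.sw_score:6d} 10.0  0.5  0.5  {t.chrom} {t.start + 1:9d} {t.end:9d} "
                f"(0) {strand} {t.repeat_name:12s} {classfam:18s} 1 {t.end - t.start:5d} "
                f"(0) {i}{star}\n"
            )


def _write_gtf(genes: Sequence[GeneInterval], path) -> None:
    with open(path, "wt") as fh:
        fh.write("#!genome synthetic\n")
        for i, g in enumerate(genes, start=1):
            attrs = (
                f'gene_id "ENSS{i:011d}"; gene_name "{g.gene_id}"; '
                f'gene_biotype "protein_coding";'
            )
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def make_alignment_fixture(
    cfg: SimulationConfig,
    instances: Sequence[RepeatInstance],
    out_dir,
    n_samples: int | None = None,
    reads_matrix: pd.DataFrame | None = None,
):
    """Write one sorted+indexed BAM per sample with known truth counts.

    Each instance receives its configured number of fully contained MAPQ-60
    reads (``cfg.reads_per_instance`` plus jitter, or the exact per-sample
    integers of ``reads_matrix`` when given) plus one soft-clipped read whose
    *reference* span is contained (counted under the containment rule), and
    decoys that must not be counted at ``min_mapq=60``: a partially
    overlapping read, a contained MAPQ-0 read and a duplicate-flagged read.
    SAM text is written first and kept next to the BAM so fixtures stay
    inspectable.

    Returns
    -------
    dict with ``bam_paths``, ``sam_paths``, ``sample_names`` and ``truth`` —
    expected counts per instance per sample under min_mapq=60 (a read
    contained in several overlapping instances is credited to all of them).
    """
    rng = np.random.default_rng([cfg.seed, 2])
    if reads_matrix is not None:
        samples = list(reads_matrix.columns)
        n = len(samples)
    else:
        n = cfg.n_samples if n_samples is None else n_samples
        samples = [f"S{i + 1:02d}" for i in range(n)]
    os.makedirs(out_dir, exist_ok=True)
    chroms = sorted({t.chrom for t in instances})
    truth = pd.DataFrame(
        0,
        index=pd.Index([t.instance_id for t in instances], name="instance_id"),
        columns=samples,
    )
    bam_paths, sam_paths = [], []
    base = cfg.reads_per_instance
    for sample in samples:
        # (chrom, pos, flag, mapq, cigar, query_len, ref_len)
        records: list[tuple] = []
        for t in instances:
            L = min(cfg.read_length, t.end - t.start)
            if reads_matrix is not None:
                k = int(reads_matrix.at[t.instance_id, sample])
            else:
                k = int(base if isinstance(base, int) else base.get(t.instance_id, 0))
                k += int(rng.integers(0, 3))
            for _ in range(k):
                pos = int(rng.integers(t.start, t.end - L + 1))
                flag = 0 if rng.integers(2) == 0 else 16
                records.append((t.chrom, pos, flag, 60, f"{L}M", L, L))
            # soft-clipped read: clipped bases overhang the instance start,
            # but the reference span [start, start+L-10) is contained -> counted
            if L > 20:
                records.append((t.chrom, t.start, 0, 60, f"10S{L - 10}M", L, L - 10))
            # decoys for this instance, none counted at min_mapq=60:
            if t.start >= L // 2:
                records.append((t.chrom, t.start - L // 2, 0, 60, f"{L}M", L, L))  # partial
            records.append((t.chrom, t.start, 0, 0, f"{L}M", L, L))  # multi-mapper MAPQ 0
            records.append((t.chrom, t.start, 1024, 60, f"{L}M", L, L))  # PCR duplicate
        # expected counts under min_mapq=60 follow the counting rule exactly:
        # a qualifying read is credited to EVERY instance containing its
        # reference span, so overlapping instances share reads
        for chrom, pos, flag, mapq, _cigar, _qlen, rlen in records:
            if mapq < 60 or flag & 1024:
                continue
            for t in instances:
                if t.chrom == chrom and pos >= t.start and pos + rlen <= t.end:
                    truth.at[t.instance_id, sample] += 1
        sam_path = os.path.join(out_dir, f"{sample}.sam")
        with open(sam_path, "wt") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for c in chroms:
                fh.write(f"@SQ\tSN:{c}\tLN:{cfg.genome_length}\n")
            for i, (chrom, pos, flag, mapq, cigar, qlen, _rlen) in enumerate(records):
                fh.write(
                    f"r{sample}.{i}\t{flag}\t{chrom}\t{pos + 1}\t{mapq}\t{cigar}\t*\t0\t0\t"
                    f"{'A' * qlen}\t{'I' * qlen}\n"
                )
        bam_path = os.path.join(out_dir, f"{sample}.bam")
        pysam.sort("-O", "bam", "-o", bam_path, sam_path)
        pysam.index(bam_path)
        sam_paths.append(sam_path)
        bam_paths.append(bam_path)
    truth.to_csv(os.path.join(out_dir, "truth_counts.tsv"), sep="\t")
    return {
        "bam_paths": bam_paths,
        "sam_paths": sam_paths,
        "sample_names": samples,
        "truth": truth,
    }


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + mu^2*dispersion (gamma-Poisson)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_expression(
    cfg: SimulationConfig,
    links: Sequence[TEGeneLink],
    te_counts: pd.DataFrame | None = None,
):
    """Draw gene and TE count matrices from the planted linear model.

    TE terms get latent log2-CPM values uniform over
    ``baseline_logcpm_range``; TE counts are drawn negative-binomially
    around the corresponding CPM (or taken verbatim from ``te_counts`` rows
    keyed like the links, e.g. counts aggregated from a read-level fixture).
    Each gene's target log2-CPM is
    b0 + sum(planted beta * realized TE log2-CPM) + tissue effect +
    N(0, noise_sd^2), and gene counts are then drawn the same way.  The
    realized (count-derived) TE value is used as the predictor so the
    planted coefficient is the coefficient the fitted model estimates,
    free of errors-in-variables attenuation.

    Returns
    -------
    dict with ``gene_counts``, ``te_counts`` (DataFrames), ``covariates``
    (tissue: N/T alternating; patient: integer pair index) and ``truth`` —
    one row per (gene, te term) with the true beta.
    """
    if not links:
        raise ValueError("links must be non-empty")
    rng = np.random.default_rng([cfg.seed, 3])
    n = cfg.n_samples if te_counts is None else te_counts.shape[1]
    samples = [f"S{i + 1:02d}" for i in range(n)] if te_counts is None else list(te_counts.columns)
    covariates = pd.DataFrame(
        {
            "tissue": ["N" if i % 2 == 0 else "T" for i in range(n)],
            "patient": [i // 2 + 1 for i in range(n)],
        },
        index=pd.Index(samples, name="sample"),
    )
    lib = cfg.lib_size * rng.uniform(0.85, 1.15, size=n)

    te_keys = list(dict.fromkeys(lk.key for lk in links))
    if te_counts is None:
        lo, hi = cfg.baseline_logcpm_range
        latent = rng.uniform(lo, hi, size=(len(te_keys), n))
        te_mu = (2.0**latent) * lib / 1e6
        te_counts = pd.DataFrame(
            _nb_draw(rng, te_mu, cfg.nb_dispersion), index=pd.Index(te_keys, name="te_key"),
            columns=samples,
        )
    else:
        missing = set(te_keys) - set(te_counts.index)
        if missing:
            raise ValueError(f"te_counts misses link rows: {sorted(missing)[:3]}")
        te_counts = te_counts.loc[te_keys]
    realized = np.log2((te_counts.to_numpy(float) + 0.5) / (lib + 1.0) * 1e6)
    realized = pd.DataFrame(realized, index=te_keys, columns=samples)

    planted = {(g, t): b for g, t, b in cfg.planted_effects}
    genes = list(dict.fromkeys(lk.gene_id for lk in links))
    truth_rows = []
    gene_rows = {}
    for g in genes:
        b0 = float(rng.uniform(4.0, 8.0))
        tissue_eff = float(rng.normal(0.0, 0.5))
        target = np.full(n, b0)
        target += tissue_eff * (covariates["tissue"] == "T").to_numpy(float)
        for lk in links:
            if lk.gene_id != g:
                continue
            beta = planted.get((g, lk.repeat_name), 0.0)
            truth_rows.append(
                {"gene_id": g, "te_term": lk.repeat_name, "beta": beta, "beta0": b0,
                 "tissue_effect": tissue_eff}
            )
            if beta != 0.0:
                target = target + beta * realized.loc[lk.key].to_numpy()
        target += rng.normal(0.0, cfg.noise_sd, size=n)
        mu = (2.0**target) * lib / 1e6
        gene_rows[g] = _nb_draw(rng, mu, cfg.nb_dispersion)
    gene_counts = pd.DataFrame(gene_rows, index=samples).T
    gene_counts.index.name = "gene_id"
    gene_counts.columns = samples
    return {
        "gene_counts": gene_counts.astype(int),
        "te_counts": te_counts.astype(int),
        "covariates": covariates,
        "truth": pd.DataFrame(
            truth_rows, columns=["gene_id", "te_term", "beta", "beta0", "tissue_effect"]
        ),
    }


def make_full_fixture(cfg: SimulationConfig, out_dir, distance: int = 5000):
    """Generate a self-consistent input set: annotation, BAMs and counts.

    The chain: lay out genes and TEs, link them at the given window, draw
    per-instance TE expression (uniform latent log2-CPM -> NB read counts),
    write BAMs carrying exactly those reads, aggregate the BAM truth counts
    per (gene, TE subfamily), and generate gene counts from the planted
    linear model using those aggregated counts as predictors.  Running the
    real pipeline on the files therefore reproduces the truth counts exactly
    AND recovers the planted coefficients, because the predictor the model
    sees is the same quantity the generator conditioned on.

    Writes repeats.out, genes.gtf, per-sample SAM+BAM(+BAI), gene_counts.tsv,
    te_counts.tsv, covariates.tsv and truth tables; returns them in a dict.
    """
    ann = make_annotation_fixture(cfg, out_dir)
    links = find_proximal_tes(ann["genes"], ann["instances"], distance=distance)
    if not links:
        raise ValueError("fixture layout produced no TE-gene links")
    rng = np.random.default_rng([cfg.seed, 5])
    samples = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    lo, hi = cfg.baseline_logcpm_range
    ids = [t.instance_id for t in ann["instances"]]
    latent = rng.uniform(lo, hi, size=(len(ids), cfg.n_samples))
    mu = (2.0**latent) * cfg.lib_size / 1e6
    reads = pd.DataFrame(_nb_draw(rng, mu, cfg.nb_dispersion),
                         index=pd.Index(ids, name="instance_id"), columns=samples)
    aln = make_alignment_fixture(cfg, ann["instances"], out_dir, reads_matrix=reads)
    te_counts = pd.DataFrame(
        {lk.key: aln["truth"].loc[list(lk.instance_ids)].sum(axis=0) for lk in links}
    ).T
    te_counts.index.name = "te_key"
    sim = simulate_expression(cfg, links, te_counts=te_counts)
    gene_path = os.path.join(out_dir, "gene_counts.tsv")
    sim["gene_counts"].to_csv(gene_path, sep="\t", index_label="gene_id")
    te_path = os.path.join(out_dir, "te_counts.tsv")
    te_counts.to_csv(te_path, sep="\t")
    sim["covariates"].to_csv(os.path.join(out_dir, "covariates.tsv"), sep="\t")
    sim["truth"].to_csv(os.path.join(out_dir, "truth_betas.tsv"), sep="\t", index=False)
    return {
        **ann,
        **aln,
        "links": links,
        "te_counts": te_counts,
        "gene_counts": sim["gene_counts"],
        "covariates": sim["covariates"],
        "truth_betas": sim["truth"],
    }


def null_te_term_pvalues(
    n_genes: int,
    n_samples: int = 44,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """TE-term p-values under the exact null (true TE beta = 0, Gaussian noise).

    For each simulated gene: one TE predictor (uniform log2-CPM-scale values),
    tissue and patient covariates as in the paired default design, and a
    response that ignores the TE entirely.  Returns the per-gene two-sided
    p-value of the TE term from the standard fit; under the null these are
    exactly Uniform(0, 1).
    """
    rng = np.random.default_rng([seed, 4])
    n = n_samples
    samples = [f"S{i + 1:02d}" for i in range(n)]
    covariates = pd.DataFrame(
        {
            "tissue": ["N" if i % 2 == 0 else "T" for i in range(n)],
            "patient": [i // 2 + 1 for i in range(n)],
        },
        index=samples,
    )
    pvals = np.empty(n_genes)
    for g in range(n_genes):
        te = pd.DataFrame(
            rng.uniform(3.0, 7.0, size=(1, n)), index=[f"G{TE_KEY_SEP}TE"], columns=samples
        )
        spec = ModelSpec(gene_id="G", te_terms=("TE",), covariate_terms=("tissue", "patient"),
                         n=n, p=3)
        X, _ = build_design(spec, te, covariates, encoding="numeric")
        y = pd.Series(
            5.0
            + 0.4 * (covariates["tissue"] == "T").to_numpy(float)
            + rng.normal(0.0, noise_sd, size=n),
            index=samples,
            name="G",
        )
        fit = fit_gene_lm(y, X)
        pvals[g] = fit.terms.loc["TE", "p"]
    return pvals
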