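import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tegene.genes import GeneInterval
from tegene.repeats import RepeatInstance
from tegene.simulate import SimulationConfig, make_alignment_fixture, make_annotation_fixture

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=42, n_genes=4, n_samples=6, n_te_instances=26,
                            genome_length=200_000, reads_per_instance=12)


@pytest.fixture(scope="session")
def annotation_fixture(small_cfg, tmp_path_factory):
    return make_annotation_fixture(small_cfg, tmp_path_factory.mktemp("ann"))


@pytest.fixture(scope="session")
def alignment_fixture(small_cfg, annotation_fixture, tmp_path_factory):
    return make_alignment_fixture(
        small_cfg, annotation_fixture["instances"], tmp_path_factory.mktemp("aln"),
        n_samples=3,
    )


def random_layout(rng: np.random.Generator, n_genes: int, n_tes: int,
                  n_chroms: int = 3, span: int = 300_000):
    """Random genes and TEs for oracle comparisons (shared by several tests)."""
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(10_000, span - 10_000))
        genes.append(GeneInterval(
            gene_id=f"G{i}",
            chrom=str(rng.choice(chroms)),
            start=start,
            end=start + int(rng.integers(500, 5000)),
            strand=str(rng.choice(["+", "-"])),
        ))
    names = ["AluY", "L2c", "MIR3", "MLT1D", "MER5B"]
    fams = {"AluY": ("SINE", "Alu"), "L2c": ("LINE", "L2"), "MIR3": ("SINE", "MIR"),
            "MLT1D": ("LTR", "ERVL-MaLR"), "MER5B": ("DNA", "hAT-Charlie")}
    tes, seen = [], set()
    while len(tes) < n_tes:
        name = str(rng.choice(names))
        cls, fam = fams[name]
        start = int(rng.integers(0, span))
        t = RepeatInstance(
            chrom=str(rng.choice(chroms)), start=start,
            end=start + int(rng.integers(100, 500)),
            strand=str(rng.choice(["+", "-"])), repeat_name=name,
            repeat_class=cls, repeat_family=fam, sw_score=int(rng.integers(200, 3000)),
        )
        if t.instance_id not in seen:
            seen.add(t.instance_id)
            tes.append(t)
    return genes, tes


def brute_force_links(genes, tes, distance, strand_match=False, te_filter=None):
    """O(n*m) scan over all (gene, TE) pairs; the reference for linking."""
    wanted = None if te_filter is None else set(te_filter)
    out: dict[tuple[str, str], set] = {}
    for g in genes:
        for t in tes:
            if t.chrom != g.chrom:
                continue
            if wanted is not None and not (
                {t.repeat_class, t.repeat_family, t.repeat_name} & wanted
            ):
                continue
            if strand_match and t.strand != g.strand:
                continue
            d = (g.tss - t.start) if g.strand == "+" else (t.start - g.tss)
            if distance > 0:
                keep = 0 < d <= distance
            else:
                keep = -abs(distance) <= d < 0
            if keep:
                out.setdefault((g.gene_id, t.repeat_name), set()).add((t.instance_id, d))
    return out


def links_as_sets(links):
    return {
        (lk.gene_id, lk.repeat_name): set(zip(lk.instance_ids, lk.distances))
        for lk in links
    }


def naive_tmm_log2_factor(obs, ref, n_obs, n_ref, logratio_trim=0.30, abs_trim=0.05):
    """Plain transcription of the doubly-trimmed weighted mean of M values."""
    obs = np.asarray(obs, float)
    ref = np.asarray(ref, float)
    both = (obs > 0) & (ref > 0)
    o, r = obs[both], ref[both]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    var = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = len(m)

    def avg_rank(x):
        # average ranks computed by direct counting, no library call
        return np.array([(x < xi).sum() + ((x == xi).sum() + 1) / 2 for xi in x])

    rm, ra = avg_rank(m), avg_rank(a)
    lo_m, lo_a = np.floor(n * logratio_trim) + 1, np.floor(n * abs_trim) + 1
    keep = (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
    w = 1.0 / var[keep]
    return float((w * m[keep]).sum() / w.sum())


def naive_tmm_factors(counts, logratio_trim=0.30, abs_trim=0.05):
    y = counts.to_numpy(float)
    lib = y.sum(axis=0)
    f75 = np.array([np.quantile(y[:, k] / lib[k], 0.75) for k in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    logf = np.array([
        naive_tmm_log2_factor(y[:, k], y[:, ref], lib[k], lib[ref], logratio_trim, abs_trim)
        for k in range(y.shape[1])
    ])
    return 2.0 ** (logf - logf.mean())
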