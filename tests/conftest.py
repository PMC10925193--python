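import numpy as np
import pytest

from scmultidiff.core_io import GenomicInterval
from scmultidiff.simulate import plant_psi, simulate_annotation, simulate_longreads


@pytest.fixture(scope="session")
def tiny_annotation():
    """Five synthetic genes, each with one alternative internal exon."""
    return simulate_annotation(n_genes=5, exons_per_gene=3, alt_exon_frac=1.0, seed=11)


@pytest.fixture(scope="session")
def small_dataset(tiny_annotation):
    """Reads + truth for a two-group dataset with planted effects."""
    genes, alt_exons = tiny_annotation
    psi, effect = plant_psi(alt_exons, "A", "B", effect_frac=0.4, delta_psi=0.6, seed=7)
    reads, truth = simulate_longreads(
        genes,
        alt_exons,
        group_cells={"A": 20, "B": 20},
        psi_true=psi,
        reads_per_cell=30,
        umi_dup_rate=0.15,
        seed=13,
    )
    return genes, alt_exons, psi, effect, reads, truth


def iv(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand)


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook dynamic-programming Levenshtein distance (independent oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_force_umi_clusters(umis, min_distance=4):
    """Single-linkage clusters by repeated merging (independent oracle)."""
    clusters = [{i} for i in range(len(umis))]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(
                    levenshtein_dp(umis[a], umis[b]) < min_distance
                    for a in clusters[i]
                    for b in clusters[j]
                ):
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(c) for c in clusters}


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer hypergeometric enumeration."""
    from math import comb

    n1, n2 = a + b, c + d
    m = a + c
    weights = {
        k: comb(n1, k) * comb(n2, m - k)
        for k in range(max(0, m - n2), min(n1, m) + 1)
    }
    w_obs = weights[a]
    return sum(w for w in weights.values() if w <= w_obs) / comb(n1 + n2, m)
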