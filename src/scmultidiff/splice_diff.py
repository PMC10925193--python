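"""Differential exon inclusion between two cell groups.

For each exon with enough informative molecules in both groups, the percent
spliced in Psi = inc / (inc + exc) is estimated per group and the 2x2 table
[[inc_A, exc_A], [inc_B, exc_B]] is tested with a two-sided Fisher exact test.
P-values are corrected with Benjamini-Yekutieli (valid under arbitrary
dependence) within the comparison, and an exon is called significant when
p_adj < alpha and |delta Psi| >= min_dpsi. Optionally at most ``max_per_gene``
significant exons are kept per gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, fisher_exact
from statsmodels.stats.multitest import multipletests

from .core_io import GenomicInterval

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_DPSI = 0.1
DEFAULT_MIN_READS = 10
DEFAULT_MAX_PER_GENE = 5

ExonKey = tuple[str, GenomicInterval]  # (gene_id, exon interval)


class ExonInclusionTable:
    """Per-(exon, group) inclusion and exclusion molecule counts."""

    def __init__(self) -> None:
        self._counts: dict[ExonKey, dict[str, list[int]]] = {}

    def add(
        self, gene_id: str, exon: GenomicInterval, group: str, inc: int = 0, exc: int = 0
    ) -> None:
        cell = self._counts.setdefault((gene_id, exon), {}).setdefault(group, [0, 0])
        cell[0] += inc
        cell[1] += exc

    def set_counts(
        self, gene_id: str, exon: GenomicInterval, group: str, inc: int, exc: int
    ) -> None:
        self._counts.setdefault((gene_id, exon), {})[group] = [inc, exc]

    def exons(self) -> list[ExonKey]:
        return sorted(self._counts, key=lambda k: (k[1].chrom, k[1].start, k[1].end, k[0]))

    def groups(self) -> list[str]:
        return sorted({g for d in self._counts.values() for g in d})

    def counts(self, key: ExonKey, group: str) -> tuple[int, int]:
        inc, exc = self._counts.get(key, {}).get(group, (0, 0))
        return inc, exc

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, key: ExonKey) -> bool:
        return key in self._counts

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tchrom\tstart\tend\tgroup\tinc\texc\n")
            for gene_id, exon in self.exons():
                for group in sorted(self._counts[(gene_id, exon)]):
                    inc, exc = self.counts((gene_id, exon), group)
                    fh.write(
                        f"{gene_id}\t{exon.chrom}\t{exon.start}\t{exon.end}\t{group}\t{inc}\t{exc}\n"
                    )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExonInclusionTable":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "group": str})
        table = cls()
        for r in df.itertuples():
            table.add(
                r.gene,
                GenomicInterval(r.chrom, int(r.start), int(r.end)),
                r.group,
                inc=int(r.inc),
                exc=int(r.exc),
            )
        return table


@dataclass(frozen=True)
class PsiEstimate:
    inc: int
    exc: int

    @property
    def n(self) -> int:
        return self.inc + self.exc

    @property
    def psi(self) -> float:
        if self.n == 0:
            return float("nan")
        return self.inc / self.n


@lru_cache(maxsize=1_000_000)
def fisher_two_sided(inc_a: int, exc_a: int, inc_b: int, exc_b: int) -> float:
    """Two-sided Fisher exact p for [[inc_a, exc_a], [inc_b, exc_b]] (cached)."""
    _, p = fisher_exact([[inc_a, exc_a], [inc_b, exc_b]], alternative="two-sided")
    return float(p)


def fisher_one_sided(
    inc_a: int, exc_a: int, inc_b: int, exc_b: int, alternative: str = "greater"
) -> float:
    _, p = fisher_exact([[inc_a, exc_a], [inc_b, exc_b]], alternative=alternative)
    return float(p)


def test_exon(
    inc_a: int,
    exc_a: int,
    inc_b: int,
    exc_b: int,
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[float, float] | None:
    """Delta-Psi (A - B) and two-sided Fisher p for one exon; None if either
    group has fewer than ``min_reads`` informative molecules (untested)."""
    if inc_a + exc_a < min_reads or inc_b + exc_b < min_reads:
        return None
    delta = inc_a / (inc_a + exc_a) - inc_b / (inc_b + exc_b)
    return delta, fisher_two_sided(inc_a, exc_a, inc_b, exc_b)


def adjust_by(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment with penalty c(m) = sum_{i<=m} 1/i."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_dpsi: float = DEFAULT_MIN_DPSI,
) -> pd.DataFrame:
    """Flag exons with p_adj < alpha and |delta_psi| >= min_dpsi."""
    results = results.copy()
    results["significant"] = (results["p_adj"] < alpha) & (
        results["delta_psi"].abs() >= min_dpsi
    )
    return results


def cap_per_gene(
    results: pd.DataFrame, max_per_gene: int = DEFAULT_MAX_PER_GENE
) -> pd.DataFrame:
    """Keep at most ``max_per_gene`` significant exons per gene.

    Kept are the smallest p_adj (ties: larger |delta_psi|, then leftmost
    start); the rest are demoted to non-significant with capped_out=True.
    """
    results = results.copy()
    results["capped_out"] = False
    sig = results.index[results["significant"]]
    if len(sig) == 0:
        return results
    sub = results.loc[sig]
    order = sub.sort_values(
        by=["p_adj", "delta_psi", "start"],
        key=lambda s: -s.abs() if s.name == "delta_psi" else s,
        kind="mergesort",
    )
    demote = order.groupby("gene", sort=False).cumcount() >= max_per_gene
    demoted_idx = order.index[demote]
    results.loc[demoted_idx, "significant"] = False
    results.loc[demoted_idx, "capped_out"] = True
    return results


@dataclass(frozen=True)
class DirectionBias:
    """Fraction of significant exons whose inclusion shift points one way."""

    n_toward: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_toward / self.n_total

    @property
    def p_value(self) -> float:
        return binomtest(self.n_toward, self.n_total, 0.5).pvalue


def direction_bias(delta_psis: Iterable[float]) -> DirectionBias:
    """Count significant exons with positive delta_psi (toward group A)
    against an even split; exact two-sided binomial test vs 0.5."""
    deltas = [d for d in delta_psis if d != 0]
    if not deltas:
        raise ValueError("direction_bias requires at least one signed delta_psi")
    return DirectionBias(sum(d > 0 for d in deltas), len(deltas))


def run_differential_splicing(
    table: ExonInclusionTable,
    group_a: str,
    group_b: str,
    alpha: float = DEFAULT_ALPHA,
    min_dpsi: float = DEFAULT_MIN_DPSI,
    min_reads: int = DEFAULT_MIN_READS,
    max_per_gene: int | None = DEFAULT_MAX_PER_GENE,
    correction: str = "by",
) -> pd.DataFrame:
    """Run the full two-group differential exon inclusion analysis.

    Returns one row per exon passing min_reads in both groups, with Psi per
    group, delta_psi (A - B), raw and adjusted p, and significance flags.
    """
    rows = []
    for gene_id, exon in table.exons():
        inc_a, exc_a = table.counts((gene_id, exon), group_a)
        inc_b, exc_b = table.counts((gene_id, exon), group_b)
        out = test_exon(inc_a, exc_a, inc_b, exc_b, min_reads=min_reads)
        if out is None:
            continue
        delta, p = out
        rows.append(
            {
                "gene": gene_id,
                "chrom": exon.chrom,
                "start": exon.start,
                "end": exon.end,
                "inc_a": inc_a,
                "exc_a": exc_a,
                "inc_b": inc_b,
                "exc_b": exc_b,
                "psi_a": PsiEstimate(inc_a, exc_a).psi,
                "psi_b": PsiEstimate(inc_b, exc_b).psi,
                "delta_psi": delta,
                "p_raw": p,
            }
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "gene", "chrom", "start", "end", "inc_a", "exc_a", "inc_b", "exc_b",
            "psi_a", "psi_b", "delta_psi", "p_raw",
        ],
    )
    if len(results) == 0:
        results["p_adj"] = pd.Series(dtype=float)
        results["significant"] = pd.Series(dtype=bool)
        results["capped_out"] = pd.Series(dtype=bool)
        return results
    adjust = adjust_by if correction == "by" else adjust_bh
    results["p_adj"] = adjust(results["p_raw"].to_numpy())
    results = call_significant(results, alpha=alpha, min_dpsi=min_dpsi)
    if max_per_gene is not None:
        results = cap_per_gene(results, max_per_gene=max_per_gene)
    else:
        results["capped_out"] = False
    return results


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
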