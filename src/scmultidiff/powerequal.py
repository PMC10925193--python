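"""Downsampling framework that equalizes statistical power across cell groups.

Cell groups differ in cell numbers, sequencing depth and numbers of testable
units, so raw %-significant figures are not comparable between groups. The
framework repeatedly subsamples each comparison to a fixed budget — a fixed
number of reads per exon and exons per iteration for splicing; a fixed number
of cells per group and peaks per iteration for chromatin — reruns the
differential test on each subsample, and records the percentage of tests that
pass. The resulting per-iteration distributions are comparable across groups
of unequal depth and are contrasted with Wilcoxon rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon

from .atac_diff import PeakMatrix, filter_peaks, run_differential_peaks
from .splice_diff import (
    ExonInclusionTable,
    adjust_bh,
    adjust_by,
    fisher_two_sided,
)


@dataclass(frozen=True)
class DownsampleConfig:
    """Budgets for one downsampling run.

    Splicing defaults follow the study design of 20 reads per exon per group,
    100 exons per iteration with at most one exon per gene, and 100 iterations;
    chromatin defaults follow 1,000 cells per group, 10,000 peaks (5,000 per
    category when stratified) and 20 iterations.
    """

    modality: str  # "splice" | "atac"
    reads_per_exon: int = 20
    exons_per_iter: int = 100
    exons_per_gene: int = 1
    cells_per_group: int = 1000
    peaks_per_iter: int = 10_000
    peaks_per_category: int = 5_000
    iterations: int | None = None
    alpha: float = 0.05
    min_dpsi: float = 0.1
    min_cell_frac: float = 0.02
    apply_dpsi_filter: bool = True
    balanced_reads: bool = True  # reads_per_exon is per group (not total)
    correction: str | None = None  # default: BY for splice, BH for atac
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("splice", "atac"):
            raise ValueError(f"modality must be 'splice' or 'atac', got {self.modality!r}")
        for name in (
            "reads_per_exon", "exons_per_iter", "exons_per_gene",
            "cells_per_group", "peaks_per_iter", "peaks_per_category",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_iterations < 2:
            raise ValueError("iterations must be >= 2")

    @property
    def n_iterations(self) -> int:
        if self.iterations is not None:
            return self.iterations
        return 100 if self.modality == "splice" else 20

    @property
    def adjust(self):
        method = self.correction or ("by" if self.modality == "splice" else "bh")
        return adjust_by if method == "by" else adjust_bh


@dataclass
class DownsampleDistribution:
    """Per-iteration %-significant values for one cell-group comparison."""

    comparison: str
    values: np.ndarray  # percentages in [0, 100], one per iteration
    shortfalls: list[int] = field(default_factory=list)  # units short per iteration

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 100)):
            raise ValueError("per-iteration percentages must lie in [0, 100]")

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def quartiles(self) -> tuple[float, float]:
        q1, q3 = np.percentile(self.values, [25, 75])
        return float(q1), float(q3)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "comparison": self.comparison,
                "iteration": np.arange(len(self.values)),
                "pct_significant": self.values,
                "shortfall": self.shortfalls or 0,
            }
        )

    def summary(self) -> dict:
        q1, q3 = self.quartiles
        return {
            "comparison": self.comparison,
            "median": self.median,
            "q1": q1,
            "q3": q3,
            "iterations": len(self.values),
            "total_shortfall": int(sum(self.shortfalls)),
        }


def downsample_splice(
    table: ExonInclusionTable,
    group_a: str,
    group_b: str,
    cfg: DownsampleConfig,
    comparison: str | None = None,
) -> DownsampleDistribution:
    """Power-equalized %-significant distribution for one splicing comparison.

    Per iteration: restrict to exons with enough informative molecules in both
    groups, sample at most ``exons_per_gene`` eligible exons per gene and then
    ``exons_per_iter`` exons without replacement, subsample ``reads_per_exon``
    molecules per exon and group (a hypergeometric draw of inclusions), rerun
    the Fisher tests with FDR correction within the iteration, and record
    100 * #significant / #tested. Deterministic given the config seed.
    """
    if cfg.modality != "splice":
        raise ValueError("downsample_splice requires a splice-modality config")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.reads_per_exon

    eligible: dict[str, list] = {}
    counts: dict = {}
    for key in table.exons():
        ia, ea = table.counts(key, group_a)
        ib, eb = table.counts(key, group_b)
        if ia + ea >= n and ib + eb >= n:
            eligible.setdefault(key[0], []).append(key)
            counts[key] = (ia, ea, ib, eb)
    if not eligible:
        raise ValueError(
            f"no exon has >= {n} informative molecules in both {group_a!r} and "
            f"{group_b!r}; reads_per_exon is the binding constraint"
        )
    gene_order = sorted(eligible)

    values = np.empty(cfg.n_iterations)
    shortfalls: list[int] = []
    for it in range(cfg.n_iterations):
        pool = []
        for gene in gene_order:
            keys = eligible[gene]
            if len(keys) <= cfg.exons_per_gene:
                pool.extend(keys)
            else:
                idx = rng.choice(len(keys), size=cfg.exons_per_gene, replace=False)
                pool.extend(keys[i] for i in sorted(idx))
        if len(pool) <= cfg.exons_per_iter:
            sampled = pool
            shortfalls.append(cfg.exons_per_iter - len(pool))
        else:
            idx = rng.choice(len(pool), size=cfg.exons_per_iter, replace=False)
            sampled = [pool[i] for i in sorted(idx)]
            shortfalls.append(0)

        deltas = np.empty(len(sampled))
        pvals = np.empty(len(sampled))
        for i, key in enumerate(sampled):
            ia, ea, ib, eb = counts[key]
            sa = int(rng.hypergeometric(ia, ea, n))  # inclusions among n draws
            sb = int(rng.hypergeometric(ib, eb, n))
            deltas[i] = sa / n - sb / n
            pvals[i] = fisher_two_sided(sa, n - sa, sb, n - sb)
        p_adj = cfg.adjust(pvals)
        sig = p_adj < cfg.alpha
        if cfg.apply_dpsi_filter:
            sig &= np.abs(deltas) >= cfg.min_dpsi
        values[it] = 100.0 * sig.sum() / len(sampled)

    return DownsampleDistribution(
        comparison=comparison or f"{group_a}_vs_{group_b}",
        values=values,
        shortfalls=shortfalls,
    )


def downsample_atac(
    matrix: PeakMatrix,
    group_a: str,
    group_b: str,
    cfg: DownsampleConfig,
    stratify_by_category: bool = False,
    comparison: str | None = None,
) -> DownsampleDistribution | dict[str, DownsampleDistribution]:
    """Power-equalized %-significant distribution(s) for one chromatin comparison.

    Per iteration: sample ``cells_per_group`` cells per group without
    replacement, re-apply the 2%-of-sampled-cells detection filter, restrict to
    peaks in the vicinity of target genes (when the matrix carries an
    ``in_target`` annotation), sample ``peaks_per_iter`` peaks (or
    ``peaks_per_category`` per category when stratified), run the exact
    detection test with FDR correction within the iteration, and record the
    percentage of significant tests. Deterministic given the config seed.
    """
    if cfg.modality != "atac":
        raise ValueError("downsample_atac requires an atac-modality config")
    rng = np.random.default_rng(cfg.seed)
    idx_a = np.flatnonzero(matrix.group_mask(group_a))
    idx_b = np.flatnonzero(matrix.group_mask(group_b))
    if len(idx_a) < cfg.cells_per_group or len(idx_b) < cfg.cells_per_group:
        raise ValueError(
            f"both groups need >= {cfg.cells_per_group} cells; got "
            f"{group_a}: {len(idx_a)}, {group_b}: {len(idx_b)}"
        )
    ann = matrix.annotations
    in_target = (
        ann["in_target"].to_numpy()
        if ann is not None and "in_target" in ann
        else np.ones(matrix.n_peaks, dtype=bool)
    )
    categories = (
        ann["category"].to_numpy()
        if stratify_by_category and ann is not None and "category" in ann
        else None
    )
    if stratify_by_category and categories is None:
        raise ValueError("stratify_by_category requires a 'category' peak annotation")

    label = comparison or f"{group_a}_vs_{group_b}"
    strata = sorted(set(categories[in_target])) if stratify_by_category else [None]
    values = {s: np.empty(cfg.n_iterations) for s in strata}
    shortfalls = {s: [] for s in strata}

    det = matrix.detected()
    for it in range(cfg.n_iterations):
        cells_a = rng.choice(idx_a, size=cfg.cells_per_group, replace=False)
        cells_b = rng.choice(idx_b, size=cfg.cells_per_group, replace=False)
        cells = np.concatenate([np.sort(cells_a), np.sort(cells_b)])
        sub = det[cells]
        det_per_peak = np.asarray(sub.sum(axis=0)).ravel()
        passing = det_per_peak / len(cells) >= cfg.min_cell_frac
        passing &= in_target
        k_a = np.asarray(sub[: cfg.cells_per_group].sum(axis=0)).ravel().astype(int)
        k_b = np.asarray(sub[cfg.cells_per_group :].sum(axis=0)).ravel().astype(int)

        for stratum in strata:
            if stratum is None:
                cand = np.flatnonzero(passing)
                budget = cfg.peaks_per_iter
            else:
                cand = np.flatnonzero(passing & (categories == stratum))
                budget = cfg.peaks_per_category
            if len(cand) == 0:
                values[stratum][it] = 0.0
                shortfalls[stratum].append(budget)
                continue
            if len(cand) <= budget:
                chosen = cand
                shortfalls[stratum].append(budget - len(cand))
            else:
                chosen = np.sort(rng.choice(cand, size=budget, replace=False))
                shortfalls[stratum].append(0)
            pvals = np.array(
                [
                    _cached_fisher(k_a[j], cfg.cells_per_group, k_b[j], cfg.cells_per_group)
                    for j in chosen
                ]
            )
            p_adj = cfg.adjust(pvals)
            values[stratum][it] = 100.0 * (p_adj < cfg.alpha).sum() / len(chosen)

    if not stratify_by_category:
        return DownsampleDistribution(label, values[None], shortfalls[None])
    return {
        s: DownsampleDistribution(f"{label}[{s}]", values[s], shortfalls[s])
        for s in strata
    }


def _cached_fisher(k_a: int, n_a: int, k_b: int, n_b: int) -> float:
    return fisher_two_sided(k_a, n_a - k_a, k_b, n_b - k_b)


def compare_distributions(
    d1: DownsampleDistribution | Sequence[float],
    d2: DownsampleDistribution | Sequence[float],
    paired: bool = False,
) -> tuple[float, float]:
    """Contrast two %-significant distributions with a Wilcoxon rank test.

    Unpaired: rank-sum (Mann-Whitney U), exact when both samples have <= 25
    values and no ties, otherwise the normal approximation with tie
    correction. Paired: Wilcoxon signed-rank on per-iteration differences.
    Returns (statistic, two-sided p).
    """
    x = np.asarray(d1.values if isinstance(d1, DownsampleDistribution) else d1, float)
    y = np.asarray(d2.values if isinstance(d2, DownsampleDistribution) else d2, float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired comparison requires equal-length distributions")
        diff = x - y
        if np.all(diff == 0):
            return 0.0, 1.0
        res = wilcoxon(x, y)
        return float(res.statistic), float(res.pvalue)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GeneStrata:
    """Partition of target genes into disease-only, synaptic-only, and both."""

    disease_only: set[str]
    synaptic_only: set[str]
    both: set[str]
    overlap_fraction: float  # fraction of synaptic genes also disease-associated

    def as_dict(self) -> dict[str, set[str]]:
        return {
            "D+S-": self.disease_only,
            "D-S+": self.synaptic_only,
            "D+S+": self.both,
        }


def stratify_genes(disease_set: Iterable[str], synaptic_set: Iterable[str]) -> GeneStrata:
    """Split genes into D+S- / D-S+ / D+S+; genes in neither set are excluded."""
    disease = set(disease_set)
    synaptic = set(synaptic_set)
    both = disease & synaptic
    return GeneStrata(
        disease_only=disease - synaptic,
        synaptic_only=synaptic - disease,
        both=both,
        overlap_fraction=(len(both) / len(synaptic)) if synaptic else 0.0,
    )


def write_distributions(
    dists: Iterable[DownsampleDistribution], path: str | Path
) -> None:
    pd.concat([d.to_frame() for d in dists], ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_summary(dists: Iterable[DownsampleDistribution], path: str | Path) -> None:
    pd.DataFrame([d.summary() for d in dists]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
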