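"""Fragment-in-peak counting and two-group differential chromatin accessibility.

The unit of evidence is the binarized cell x peak signal: a peak is "detected"
in a cell when at least one fragment of that barcode overlaps it. Peaks seen in
fewer than 2% of the cells entering a comparison are dropped, the remaining
peaks are tested per peak with a two-sided Fisher exact test on detection
(or a depth-adjusted logistic likelihood-ratio test), and p-values are
corrected with Benjamini-Hochberg within the comparison. Peak context
(UTR/exon/intron/intergenic), nearest-gene vicinity, and basepair/count
Jaccard similarity between peak sets are computed here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import sparse
from scipy.stats import fisher_exact

from .core_io import (
    FragmentRecord,
    GeneCollection,
    GenomicInterval,
    merge_intervals,
)
from .splice_diff import adjust_bh, adjust_by

DEFAULT_MIN_CELL_FRAC = 0.02
DEFAULT_MIN_CELLS = 20
DEFAULT_MAX_VICINITY_DIST = 50_000
#: pseudo-fraction added to detection fractions before the log2 effect size
EFFECT_EPSILON = 1e-3

PEAK_CATEGORIES = ("UTR", "exon", "intron", "intergenic")


@dataclass
class PeakMatrix:
    """Sparse cells x peaks fragment counts plus peak metadata.

    ``counts[i, j]`` is the duplicate-weighted number of fragments of cell i
    overlapping peak j. ``annotations`` (optional) carries per-peak category,
    nearest_gene, distance and in_target columns from :func:`annotate_peaks`.
    """

    peaks: list[GenomicInterval]
    barcodes: list[str]
    groups: np.ndarray  # group label per cell, aligned with barcodes
    counts: sparse.csr_matrix
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.barcodes), len(self.peaks)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} cells x {len(self.peaks)} peaks"
            )
        if len(self.groups) != len(self.barcodes):
            raise ValueError("one group label per cell required")
        if self.annotations is not None and len(self.annotations) != len(self.peaks):
            raise ValueError("one annotation row per peak required")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def detected(self) -> sparse.csr_matrix:
        """Binarized detection matrix (count > 0)."""
        out = self.counts.copy()
        out.data = np.ones_like(out.data)
        return out

    def detection_counts(self, cell_mask: np.ndarray | None = None) -> np.ndarray:
        """Number of cells detecting each peak (optionally within a cell mask)."""
        det = self.detected()
        if cell_mask is not None:
            det = det[cell_mask]
        return np.asarray(det.sum(axis=0)).ravel().astype(int)

    def group_mask(self, group: str) -> np.ndarray:
        return self.groups == group

    def subset_cells(self, mask: np.ndarray) -> "PeakMatrix":
        return PeakMatrix(
            peaks=self.peaks,
            barcodes=[b for b, m in zip(self.barcodes, mask) if m],
            groups=self.groups[mask],
            counts=self.counts[mask],
            annotations=self.annotations,
        )

    def subset_peaks(self, mask: np.ndarray) -> "PeakMatrix":
        idx = np.flatnonzero(mask)
        return PeakMatrix(
            peaks=[self.peaks[i] for i in idx],
            barcodes=self.barcodes,
            groups=self.groups,
            counts=self.counts[:, idx],
            annotations=(
                self.annotations.iloc[idx].reset_index(drop=True)
                if self.annotations is not None
                else None
            ),
        )


def count_fragments_in_peaks(
    fragments: Iterable[FragmentRecord],
    peaks: Sequence[GenomicInterval],
    barcode_to_group: Mapping[str, str],
) -> tuple[PeakMatrix, int]:
    """Build the cells x peaks count matrix.

    A fragment overlapping k peaks (by >= 1 bp) increments all k, weighted by
    its duplicate count. Fragments whose barcode is not in the comparison are
    ignored and counted; returns (matrix, n_ignored).
    """
    barcodes = sorted(barcode_to_group)
    cell_idx = {b: i for i, b in enumerate(barcodes)}
    trees: dict[str, IntervalTree] = {}
    for j, p in enumerate(peaks):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, j)

    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    n_ignored = 0
    for frag in fragments:
        i = cell_idx.get(frag.barcode)
        if i is None:
            n_ignored += 1
            continue
        tree = trees.get(frag.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(frag.interval.start, frag.interval.end):
            rows.append(i)
            cols.append(hit.data)
            data.append(frag.count)
    counts = sparse.coo_matrix(
        (data, (rows, cols)), shape=(len(barcodes), len(peaks)), dtype=np.int64
    ).tocsr()
    groups = np.array([barcode_to_group[b] for b in barcodes])
    return PeakMatrix(list(peaks), barcodes, groups, counts), n_ignored


def filter_peaks(
    matrix: PeakMatrix, min_cell_frac: float = DEFAULT_MIN_CELL_FRAC
) -> PeakMatrix:
    """Keep peaks detected in at least ``min_cell_frac`` of all cells in the
    comparison (the 2%-of-cells rule)."""
    if matrix.n_cells == 0:
        return matrix
    det = matrix.detection_counts()
    keep = det / matrix.n_cells >= min_cell_frac
    return matrix.subset_peaks(keep)


@lru_cache(maxsize=1_000_000)
def _fisher_detection(k_a: int, n_a: int, k_b: int, n_b: int) -> float:
    _, p = fisher_exact([[k_a, n_a - k_a], [k_b, n_b - k_b]], alternative="two-sided")
    return float(p)


def _lr_depth_p(
    det: np.ndarray, is_a: np.ndarray, log_depth: np.ndarray
) -> float:
    """Likelihood-ratio p for group effect on detection, adjusting for depth."""
    import statsmodels.api as sm
    from scipy.stats import chi2

    x_full = np.column_stack([np.ones_like(log_depth), log_depth, is_a.astype(float)])
    x_red = x_full[:, :2]
    try:
        full = sm.GLM(det, x_full, family=sm.families.Binomial()).fit(maxiter=100)
        red = sm.GLM(det, x_red, family=sm.families.Binomial()).fit(maxiter=100)
        lr = 2 * (full.llf - red.llf)
        return float(chi2.sf(max(lr, 0.0), df=1))
    except Exception:
        # perfect separation or non-convergence: fall back to the exact test
        n_a = int(is_a.sum())
        return _fisher_detection(
            int(det[is_a].sum()), n_a, int(det[~is_a].sum()), len(det) - n_a
        )


def run_differential_peaks(
    matrix: PeakMatrix,
    group_a: str,
    group_b: str,
    method: str = "fisher_binary",
    alpha: float = 0.05,
    min_cells: int = DEFAULT_MIN_CELLS,
    correction: str = "bh",
) -> pd.DataFrame:
    """Two-group differential accessibility over every peak of the matrix.

    ``fisher_binary`` tests detection counts [[k_A, n_A - k_A], [k_B, n_B - k_B]]
    exactly; ``lr_depth`` runs a logistic likelihood-ratio test of detection on
    group with log total fragment count per cell as covariate. The effect size
    is log2((frac_A + eps) / (frac_B + eps)) with eps = 1e-3.
    """
    mask_a = matrix.group_mask(group_a)
    mask_b = matrix.group_mask(group_b)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < min_cells or n_b < min_cells:
        raise ValueError(
            f"both groups need >= {min_cells} cells; got {group_a}: {n_a}, "
            f"{group_b}: {n_b}"
        )
    k_a = matrix.detection_counts(mask_a)
    k_b = matrix.detection_counts(mask_b)
    frac_a = k_a / n_a
    frac_b = k_b / n_b
    effect = np.log2((frac_a + EFFECT_EPSILON) / (frac_b + EFFECT_EPSILON))

    if method == "fisher_binary":
        p_raw = np.array(
            [_fisher_detection(int(ka), n_a, int(kb), n_b) for ka, kb in zip(k_a, k_b)]
        )
    elif method == "lr_depth":
        keep = mask_a | mask_b
        det_all = (matrix.detected()[keep]).toarray().astype(float)
        depth = np.asarray(matrix.counts[keep].sum(axis=1)).ravel()
        log_depth = np.log1p(depth)
        is_a = mask_a[keep]
        p_raw = np.array(
            [_lr_depth_p(det_all[:, j], is_a, log_depth) for j in range(matrix.n_peaks)]
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    results = pd.DataFrame(
        {
            "chrom": [p.chrom for p in matrix.peaks],
            "start": [p.start for p in matrix.peaks],
            "end": [p.end for p in matrix.peaks],
            "frac_a": frac_a,
            "frac_b": frac_b,
            "effect": effect,
            "p_raw": p_raw,
        }
    )
    if len(results):
        adjust = adjust_bh if correction == "bh" else adjust_by
        results["p_adj"] = adjust(p_raw)
        results["significant"] = results["p_adj"] < alpha
    else:
        results["p_adj"] = pd.Series(dtype=float)
        results["significant"] = pd.Series(dtype=bool)
    if matrix.annotations is not None:
        results = pd.concat(
            [results, matrix.annotations.reset_index(drop=True)], axis=1
        )
    return results


def assign_vicinity(
    peaks: Sequence[GenomicInterval],
    genes: GeneCollection,
    target_genes: set[str] | frozenset,
    max_dist: int = DEFAULT_MAX_VICINITY_DIST,
) -> pd.DataFrame:
    """Nearest gene (by gene-body distance) per peak and a target-vicinity flag.

    Distance 0 when peak and gene body overlap; ties are broken by distance to
    the TSS, then lexicographic gene_id. ``in_target`` is true iff the nearest
    gene is in ``target_genes`` and its distance is <= ``max_dist``.
    """
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)

    nearest: list[str | None] = []
    dists: list[float] = []
    flags: list[bool] = []
    for peak in peaks:
        cands = by_chrom.get(peak.chrom, [])
        best: tuple[int, int, str] | None = None
        for g in cands:
            d = peak.distance(g.interval)
            tss_d = min(abs(g.tss - peak.start), abs(g.tss - peak.end))
            if peak.contains_point(g.tss):
                tss_d = 0
            key = (d, tss_d, g.gene_id)
            if best is None or key < best:
                best = key
        if best is None:
            nearest.append(None)
            dists.append(np.nan)
            flags.append(False)
        else:
            d, _, gid = best
            nearest.append(gid)
            dists.append(d)
            flags.append(gid in target_genes and d <= max_dist)
    return pd.DataFrame(
        {"nearest_gene": nearest, "distance": dists, "in_target": flags}
    )


def categorize_peak(peak: GenomicInterval, genes: GeneCollection) -> str:
    """Genomic context of a peak's midpoint with precedence UTR > exon > intron
    (inside a gene body but no exon) > intergenic."""
    mid = peak.midpoint
    hits = genes.overlapping(peak.chrom, mid, mid + 1)
    if not hits:
        return "intergenic"
    in_exon = False
    for g in hits:
        for u in g.utrs:
            if u.contains_point(mid):
                return "UTR"
        if not in_exon:
            in_exon = any(e.contains_point(mid) for e in g.exons)
    return "exon" if in_exon else "intron"


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    genes: GeneCollection,
    target_genes: set[str] | frozenset,
    max_dist: int = DEFAULT_MAX_VICINITY_DIST,
) -> pd.DataFrame:
    """Vicinity plus category annotation for a peak list (one row per peak)."""
    ann = assign_vicinity(peaks, genes, target_genes, max_dist=max_dist)
    ann["category"] = [categorize_peak(p, genes) for p in peaks]
    return ann


def jaccard(
    peaks_a: Iterable[GenomicInterval],
    peaks_b: Iterable[GenomicInterval],
    mode: str = "basepair",
) -> float | None:
    """Jaccard similarity of two peak sets (each merged first).

    basepair: intersected bp / union bp. count: symmetric overlap-count
    variant — (#A peaks touching B + #B peaks touching A) / (#A + #B).
    Returns None when both sets are empty (undefined).
    """
    a = merge_intervals(peaks_a)
    b = merge_intervals(peaks_b)
    if not a and not b:
        return None
    if mode == "basepair":
        inter = _intersect_bp(a, b)
        union = sum(len(iv) for iv in a) + sum(len(iv) for iv in b) - inter
        return inter / union
    if mode == "count":
        n_a_hit = sum(any(x.overlaps(y) for y in b) for x in a)
        n_b_hit = sum(any(y.overlaps(x) for x in a) for y in b)
        return (n_a_hit + n_b_hit) / (len(a) + len(b))
    raise ValueError(f"unknown jaccard mode {mode!r}")


def _intersect_bp(a: list[GenomicInterval], b: list[GenomicInterval]) -> int:
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    total = 0
    for iv in a:
        for other in by_chrom_b.get(iv.chrom, []):
            total += iv.overlap_len(other)
    return total


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a detection/significance proportion."""
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=1 - conf, method="wilson")
    return float(lo), float(hi)
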