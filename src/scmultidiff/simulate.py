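"""Synthetic multiome generator with planted ground truth.

Emits exactly the inputs the pipeline reads — gene annotation, barcoded
spliced long reads, scATAC fragments, peaks, cell annotations — from a known
truth (per-exon inclusion levels Psi per group, per-peak accessibility
probabilities per group), so that every pipeline stage can be tested without
external data. All outputs are deterministic functions of (config, seed).

The generator emulates a targeted single-nucleus long-read + ATAC experiment:
genes with alternative internal exons whose inclusion is Bernoulli(Psi) per
molecule, 10-mer UMIs with optional PCR duplicates whose UMI copies carry one
substitution (so they provably collapse under the distance-4 rule and never
bridge distinct molecules), and
per-cell fragment counts over accessible peaks. It does not model sequencing
errors on genomic bases, realistic read-length distributions, doublets, or
batch effects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CellAnnotation,
    CellAnnotationTable,
    FragmentRecord,
    GeneCollection,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    merge_intervals,
    write_bed,
    write_fragments,
    write_gtf,
    write_text_list,
)
from .longread import LongReadRecord, write_bed12, write_read_sidecar
from .splice_diff import ExonInclusionTable

BASES = "ACGT"
DEFAULT_CHROM = "chrS"
#: study-scale default for high-quality fragments per cell
DEFAULT_FRAGS_PER_CELL = 7500


@dataclass
class SimTruth:
    """Planted ground truth of one simulated dataset."""

    cells: pd.DataFrame  # barcode, group, depth_factor
    psi: dict = field(default_factory=dict)  # (gene_id, (start, end)) -> {group: psi}
    access: dict = field(default_factory=dict)  # group -> per-peak probability array
    effect: dict = field(default_factory=dict)  # unit key -> planted-effect flag
    seed: int = 0

    def barcode_to_group(self) -> dict[str, str]:
        return dict(zip(self.cells["barcode"], self.cells["group"]))


def simulate_annotation(
    n_genes: int,
    exons_per_gene: int = 4,
    alt_exon_frac: float = 1.0,
    alt_exons_per_gene: int = 1,
    intron_len: int = 300,
    exon_len: int = 100,
    gene_gap: int = 2000,
    chrom: str = DEFAULT_CHROM,
    seed: int = 0,
) -> tuple[GeneCollection, list[tuple[str, GenomicInterval]]]:
    """Non-overlapping genes on one synthetic chromosome.

    Each gene has ``exons_per_gene`` constitutive exons separated by introns;
    with probability ``alt_exon_frac`` the gene hosts ``alt_exons_per_gene``
    alternative internal exons, each centered in its own intron, and gets one
    transcript including them all and one skipping them all. The first exon
    doubles as an annotated UTR. Returns the gene collection and the flagged
    alternative exons as (gene_id, interval).
    """
    if exons_per_gene < 2:
        raise ValueError("exons_per_gene must be >= 2 to host an internal alt exon")
    if intron_len < exon_len + 2:
        raise ValueError("intron_len must exceed exon_len + 2 to flank the alt exon")
    if alt_exons_per_gene > exons_per_gene - 1:
        raise ValueError("need one intron per alternative exon")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    alt_exons: list[tuple[str, GenomicInterval]] = []
    gene_len = exons_per_gene * exon_len + (exons_per_gene - 1) * intron_len
    pos = 1000
    for g in range(n_genes):
        gene_id = f"G{g:05d}"
        strand = "+" if g % 2 == 0 else "-"
        start = pos
        const = [
            GenomicInterval(
                chrom,
                start + i * (exon_len + intron_len),
                start + i * (exon_len + intron_len) + exon_len,
                strand,
            )
            for i in range(exons_per_gene)
        ]
        has_alt = rng.random() < alt_exon_frac
        transcripts = []
        if has_alt:
            alts = []
            for a in range(alt_exons_per_gene):
                intron_start = const[a].end
                alt_start = intron_start + (intron_len - exon_len) // 2
                alt = GenomicInterval(chrom, alt_start, alt_start + exon_len, strand)
                alts.append(alt)
                alt_exons.append((gene_id, alt))
            inc_exons = sorted(const + alts, key=lambda e: e.start)
            transcripts.append(
                TranscriptModel(f"{gene_id}.T1", exons=inc_exons, utrs=[const[0]])
            )
            transcripts.append(
                TranscriptModel(f"{gene_id}.T2", exons=list(const), utrs=[const[0]])
            )
        else:
            transcripts.append(
                TranscriptModel(f"{gene_id}.T1", exons=list(const), utrs=[const[0]])
            )
        interval = GenomicInterval(chrom, start, start + gene_len, strand)
        genes.append(GeneModel(gene_id, gene_id, interval, transcripts))
        pos += gene_len + gene_gap
    return GeneCollection(genes), alt_exons


def plant_psi(
    alt_exons: Sequence[tuple[str, GenomicInterval]],
    group_a: str,
    group_b: str,
    effect_frac: float = 0.0,
    delta_psi: float = 0.5,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Per-exon inclusion levels for two groups with a planted effect fraction.

    Null exons get one Psi ~ U(0.2, 0.8) shared by both groups; effect exons
    get Psi split symmetrically around 0.5 by ``delta_psi``. Returns
    (psi dict keyed like SimTruth.psi, effect-flag dict).
    """
    rng = np.random.default_rng(seed)
    psi: dict = {}
    effect: dict = {}
    for gene_id, exon in alt_exons:
        key = (gene_id, (exon.start, exon.end))
        if rng.random() < effect_frac:
            lo = float(np.clip(0.5 - delta_psi / 2, 0.0, 1.0))
            hi = float(np.clip(0.5 + delta_psi / 2, 0.0, 1.0))
            a, b = (hi, lo) if rng.random() < 0.5 else (lo, hi)
            psi[key] = {group_a: a, group_b: b}
            effect[key] = True
        else:
            base = float(rng.uniform(0.2, 0.8))
            psi[key] = {group_a: base, group_b: base}
            effect[key] = False
    return psi, effect


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        bc = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _random_umi(rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=10))


def _perturb_umi(umi: str, rng: np.random.Generator, max_subs: int = 1) -> str:
    """1..max_subs random substitutions (default one, so a duplicate stays
    within edit distance < 4 of its molecule and cannot chain two molecules
    kept >= 6 apart into one single-linkage cluster)."""
    n_subs = int(rng.integers(1, max_subs + 1))
    positions = rng.choice(len(umi), size=n_subs, replace=False)
    chars = list(umi)
    for p in positions:
        chars[p] = BASES[(BASES.index(chars[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(chars)


def simulate_longreads(
    genes: GeneCollection,
    alt_exons: Sequence[tuple[str, GenomicInterval]],
    group_cells: Mapping[str, int],
    psi_true: Mapping | float,
    reads_per_cell: int = 50,
    umi_dup_rate: float = 0.0,
    coordination: float = 0.0,
    barcode_len: int = 16,
    seed: int = 0,
) -> tuple[list[LongReadRecord], SimTruth]:
    """Barcoded spliced long reads with planted per-group exon inclusion.

    Per cell, ``reads_per_cell`` molecules are drawn: a uniform gene, then each
    alternative exon of that gene included with the cell group's Psi
    (independently across exons unless ``coordination`` couples them, in which
    case one Bernoulli draw is shared by all alt exons of the molecule). Blocks
    span the gene full length. PCR duplicates (extra reads beyond the first)
    follow a geometric law with rate ``umi_dup_rate`` and carry UMI copies with
    a single substitution; molecule UMIs within one (cell, gene) are kept at
    pairwise edit distance >= 6, so duplicates always collapse back onto their
    molecule and never bridge two molecules under the distance-4 rule. With ``umi_dup_rate`` 0, #reads == #molecules.
    """
    from .longread import edit_distance

    rng = np.random.default_rng(seed)
    gene_list = sorted(genes, key=lambda g: g.gene_id)
    if not gene_list:
        raise ValueError("need at least one gene")
    alts_by_gene: dict[str, list[GenomicInterval]] = {}
    for gene_id, exon in alt_exons:
        alts_by_gene.setdefault(gene_id, []).append(exon)

    def psi_of(gene_id: str, exon: GenomicInterval, group: str) -> float:
        if isinstance(psi_true, (int, float)):
            return float(psi_true)
        return psi_true[(gene_id, (exon.start, exon.end))][group]

    groups = sorted(group_cells)
    n_cells = sum(group_cells[g] for g in groups)
    barcodes = _random_barcodes(n_cells, barcode_len, rng)
    cell_groups = [g for g in groups for _ in range(group_cells[g])]

    reads: list[LongReadRecord] = []
    counter = itertools.count()
    for barcode, group in zip(barcodes, cell_groups):
        used_umis: dict[str, list[str]] = {}
        for _ in range(reads_per_cell):
            gene = gene_list[int(rng.integers(len(gene_list)))]
            alts = alts_by_gene.get(gene.gene_id, [])
            const = [
                e
                for e in gene.transcripts[0].exons
                if not any(e.start == a.start and e.end == a.end for a in alts)
            ]
            coordinated = len(alts) > 1 and rng.random() < coordination
            shared_draw = rng.random()
            included = list(const)
            for alt in alts:
                draw = shared_draw if coordinated else rng.random()
                if draw < psi_of(gene.gene_id, alt, group):
                    included.append(alt)
            blocks = tuple(sorted(included, key=lambda e: e.start))

            group_umis = used_umis.setdefault(gene.gene_id, [])
            for _try in range(100):
                umi = _random_umi(rng)
                if all(edit_distance(umi, u) >= 6 for u in group_umis):
                    break
            group_umis.append(umi)

            n_copies = 1
            if umi_dup_rate > 0:
                n_copies = int(rng.geometric(1.0 - umi_dup_rate))
            for copy in range(n_copies):
                read_umi = umi if copy == 0 else _perturb_umi(umi, rng)
                reads.append(
                    LongReadRecord(
                        read_id=f"r{next(counter):08d}",
                        barcode_candidate=barcode,
                        umi_candidate=read_umi,
                        chrom=gene.interval.chrom,
                        strand=gene.interval.strand,
                        blocks=blocks,
                    )
                )

    cells = pd.DataFrame(
        {"barcode": barcodes, "group": cell_groups, "depth_factor": 1.0}
    )
    psi_dict = (
        {k: dict(v) for k, v in psi_true.items()}
        if not isinstance(psi_true, (int, float))
        else {
            (gid, (e.start, e.end)): {g: float(psi_true) for g in groups}
            for gid, e in alt_exons
        }
    )
    return reads, SimTruth(cells=cells, psi=psi_dict, seed=seed)


def simulate_inclusion_counts(
    psi_by_group: Mapping[str, np.ndarray],
    depth_by_group: Mapping[str, float],
    depth_dist: str = "poisson",
    chrom: str = DEFAULT_CHROM,
    seed: int = 0,
) -> tuple[ExonInclusionTable, pd.DataFrame]:
    """Molecule-count-level simulation of an exon inclusion table.

    For power and calibration studies the read-level detail is irrelevant:
    per exon and group, the number of informative molecules is Poisson (or
    fixed) around the group's depth and inclusions are Binomial(N, Psi). Each
    exon belongs to its own gene. Returns (table, truth frame).
    """
    rng = np.random.default_rng(seed)
    groups = sorted(psi_by_group)
    n_exons = len(psi_by_group[groups[0]])
    table = ExonInclusionTable()
    rows = []
    for i in range(n_exons):
        gene_id = f"G{i:05d}"
        exon = GenomicInterval(chrom, 1000 * i + 100, 1000 * i + 200)
        for g in groups:
            depth = depth_by_group[g]
            if depth_dist == "poisson":
                n = max(1, int(rng.poisson(depth)))
            elif depth_dist == "fixed":
                n = int(depth)
            else:
                raise ValueError(f"unknown depth_dist {depth_dist!r}")
            psi = float(psi_by_group[g][i])
            inc = int(rng.binomial(n, psi))
            table.set_counts(gene_id, exon, g, inc, n - inc)
            rows.append({"gene": gene_id, "exon_start": exon.start, "group": g,
                         "psi_true": psi, "n": n, "inc": inc})
    return table, pd.DataFrame(rows)


def generate_peaks(
    n_peaks: int,
    width: int = 500,
    spacing: int = 2000,
    start: int = 1000,
    chrom: str = DEFAULT_CHROM,
) -> list[GenomicInterval]:
    """Evenly spaced non-overlapping peaks on the synthetic chromosome."""
    return [
        GenomicInterval(chrom, start + i * (width + spacing), start + i * (width + spacing) + width)
        for i in range(n_peaks)
    ]


def plant_access(
    n_peaks: int,
    group_a: str,
    group_b: str,
    base: float = 0.3,
    effect_frac: float = 0.0,
    effect_probs: tuple[float, float] = (0.1, 0.4),
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-peak accessibility probabilities for two groups.

    Null peaks share ``base`` in both groups; a planted ``effect_frac`` of
    peaks get the asymmetric pair ``effect_probs`` (direction randomized).
    Returns ({group: prob array}, effect mask).
    """
    rng = np.random.default_rng(seed)
    pa = np.full(n_peaks, base, dtype=float)
    pb = np.full(n_peaks, base, dtype=float)
    effect = rng.random(n_peaks) < effect_frac
    lo, hi = effect_probs
    flip = rng.random(n_peaks) < 0.5
    pa[effect & flip] = lo
    pb[effect & flip] = hi
    pa[effect & ~flip] = hi
    pb[effect & ~flip] = lo
    return {group_a: pa, group_b: pb}, effect


def simulate_fragments(
    peaks: Sequence[GenomicInterval],
    group_cells: Mapping[str, int],
    access_prob: Mapping[str, np.ndarray] | float,
    frags_per_cell: float = DEFAULT_FRAGS_PER_CELL,
    noise_frac: float = 0.05,
    frag_len: tuple[int, int] = (50, 300),
    barcodes: Sequence[str] | None = None,
    barcode_len: int = 16,
    seed: int = 0,
) -> tuple[list[FragmentRecord], SimTruth]:
    """scATAC fragments with planted per-group peak accessibility.

    Per cell: each peak is accessible with its group's Bernoulli probability;
    accessible peaks receive 1 + Poisson fragments (the rate set so the cell's
    expected in-peak fragment total is ``frags_per_cell``), positioned within
    the peak; a further ``noise_frac`` of fragments land uniformly outside
    peaks. Fragments carry count 1.
    """
    rng = np.random.default_rng(seed)
    groups = sorted(group_cells)
    n_peaks = len(peaks)
    if isinstance(access_prob, (int, float)):
        access = {g: np.full(n_peaks, float(access_prob)) for g in groups}
    else:
        access = {g: np.asarray(access_prob[g], dtype=float) for g in groups}
    n_cells = sum(group_cells[g] for g in groups)
    if barcodes is None:
        barcodes = _random_barcodes(n_cells, barcode_len, rng)
    elif len(barcodes) != n_cells:
        raise ValueError("barcodes length must equal total cell count")
    cell_groups = [g for g in groups for _ in range(group_cells[g])]

    merged = merge_intervals(peaks) if peaks else []
    chrom = peaks[0].chrom if peaks else DEFAULT_CHROM
    chrom_end = (merged[-1].end if merged else 0) + 100_000
    gaps = []
    cursor = 0
    for iv in merged:
        if iv.start > cursor:
            gaps.append((cursor, iv.start))
        cursor = iv.end
    gaps.append((cursor, chrom_end))
    gap_starts = np.array([g[0] for g in gaps])
    gap_lens = np.array([g[1] - g[0] for g in gaps], dtype=float)
    gap_cum = np.cumsum(gap_lens)

    peak_starts = np.array([p.start for p in peaks], dtype=int)
    peak_widths = np.array([len(p) for p in peaks], dtype=int)
    fragments: list[FragmentRecord] = []
    lo_len, hi_len = frag_len
    for barcode, group in zip(barcodes, cell_groups):
        probs = access[group]
        accessible = np.flatnonzero(rng.random(n_peaks) < probs)
        expected_accessible = max(probs.sum(), 1.0)
        extra_rate = max(0.0, frags_per_cell / expected_accessible - 1.0)
        n_frags = 1 + rng.poisson(extra_rate, size=len(accessible))
        peak_idx = np.repeat(accessible, n_frags)
        total = len(peak_idx)
        if total:
            lengths = rng.integers(lo_len, hi_len + 1, size=total)
            widths = peak_widths[peak_idx]
            lengths = np.minimum(lengths, widths)
            offsets = (rng.random(total) * (widths - lengths + 1)).astype(int)
            starts = peak_starts[peak_idx] + offsets
            for s, length in zip(starts.tolist(), lengths.tolist()):
                fragments.append(
                    FragmentRecord(GenomicInterval(chrom, s, s + length), barcode)
                )
        if noise_frac > 0 and total > 0:
            n_noise = int(rng.poisson(total * noise_frac / (1.0 - noise_frac)))
            if n_noise:
                u = rng.random(n_noise) * gap_cum[-1]
                gi = np.searchsorted(gap_cum, u, side="right")
                pos = (gap_starts[gi] + (u - (gap_cum[gi] - gap_lens[gi]))).astype(int)
                lengths = rng.integers(lo_len, hi_len + 1, size=n_noise)
                for p, length in zip(pos.tolist(), lengths.tolist()):
                    fragments.append(
                        FragmentRecord(GenomicInterval(chrom, p, p + length), barcode)
                    )

    cells = pd.DataFrame(
        {"barcode": list(barcodes), "group": cell_groups, "depth_factor": 1.0}
    )
    return fragments, SimTruth(cells=cells, access=access, seed=seed)


def simulate_peak_matrix(
    access_prob: Mapping[str, np.ndarray],
    group_cells: Mapping[str, int],
    peaks: Sequence[GenomicInterval] | None = None,
    annotations: pd.DataFrame | None = None,
    seed: int = 0,
):
    """Detection-level twin of :func:`simulate_fragments`.

    Draws the binarized cell x peak detection matrix directly from the planted
    per-group Bernoulli accessibility probabilities, skipping fragment
    placement — the right granularity for power and calibration studies of the
    detection-based differential test and the downsampling framework.
    """
    from scipy import sparse

    from .atac_diff import PeakMatrix

    rng = np.random.default_rng(seed)
    groups = sorted(group_cells)
    n_peaks = len(access_prob[groups[0]])
    if peaks is None:
        peaks = generate_peaks(n_peaks)
    rows = []
    for g in groups:
        probs = np.asarray(access_prob[g], dtype=float)
        rows.append(rng.random((group_cells[g], n_peaks)) < probs)
    det = np.vstack(rows)
    barcodes = _random_barcodes(det.shape[0], 16, rng)
    group_labels = np.array([g for g in groups for _ in range(group_cells[g])])
    return PeakMatrix(
        peaks=list(peaks),
        barcodes=barcodes,
        groups=group_labels,
        counts=sparse.csr_matrix(det.astype(np.int64)),
        annotations=annotations,
    )


def cells_to_annotation(
    cells: pd.DataFrame,
    sample_id: str = "S1",
    cell_type: str = "ExN",
    subtype: str = "",
) -> CellAnnotationTable:
    """Wrap a truth cell frame as a pipeline cell-annotation table, with the
    simulated group as the condition label."""
    return CellAnnotationTable(
        CellAnnotation(r.barcode, sample_id, cell_type, subtype, r.group)
        for r in cells.itertuples()
    )


# ---------------------------------------------------------------------------
# presets: fully written-out datasets for the CLI and determinism checks
# ---------------------------------------------------------------------------

PRESETS = ("splice-null", "splice-effect", "atac-null", "atac-effect", "multiome")


def write_preset(preset: str, outdir: str | Path, seed: int = 0) -> dict:
    """Write one self-contained dataset into ``outdir``; returns a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    manifest: dict = {"preset": preset, "seed": seed}

    if preset in ("splice-null", "splice-effect", "multiome"):
        small = preset == "multiome"
        n_genes = 100 if small else 500
        genes, alt_exons = simulate_annotation(n_genes=n_genes, seed=seed)
        effect_frac = 0.0 if preset == "splice-null" else 0.5
        psi, effect = plant_psi(
            alt_exons, "A", "B", effect_frac=effect_frac, delta_psi=0.5, seed=seed + 1
        )
        reads, truth = simulate_longreads(
            genes,
            alt_exons,
            group_cells={"A": 100 if small else 200, "B": 100 if small else 200},
            psi_true=psi,
            reads_per_cell=60 if small else 100,
            umi_dup_rate=0.1,
            seed=seed + 2,
        )
        write_gtf(genes, outdir / "annotation.gtf")
        write_bed12(reads, outdir / "reads.bed12")
        write_read_sidecar(reads, outdir / "reads_meta.tsv")
        write_text_list(truth.cells["barcode"], outdir / "whitelist.txt")
        cells_to_annotation(truth.cells).to_tsv(outdir / "cells.tsv")
        with open(outdir / "truth_psi.tsv", "w") as fh:
            fh.write("gene\tstart\tend\tgroup\tpsi\teffect\n")
            for (gid, (s, e)), per_group in sorted(psi.items()):
                for g in sorted(per_group):
                    fh.write(
                        f"{gid}\t{s}\t{e}\t{g}\t{per_group[g]:.6f}\t{int(effect[(gid, (s, e))])}\n"
                    )
        write_text_list(sorted(g.gene_id for g in genes), outdir / "targets.txt")
        manifest["n_genes"] = n_genes
        manifest["n_reads"] = len(reads)

    if preset in ("atac-null", "atac-effect", "multiome"):
        small = preset == "multiome"
        n_peaks = 500 if small else 2000
        peaks = generate_peaks(n_peaks)
        effect_frac = 0.2 if preset == "atac-effect" else 0.0
        access, effect_mask = plant_access(
            n_peaks, "A", "B", base=0.3, effect_frac=effect_frac, seed=seed + 3
        )
        frags, atruth = simulate_fragments(
            peaks,
            group_cells={"A": 150 if small else 300, "B": 150 if small else 300},
            access_prob=access,
            frags_per_cell=300 if small else 800,
            noise_frac=0.05,
            seed=seed + 4,
        )
        write_bed(peaks, outdir / "peaks.bed")
        write_fragments(frags, outdir / "fragments.tsv")
        if preset != "multiome":
            cells_to_annotation(atruth.cells).to_tsv(outdir / "cells.tsv")
            write_text_list(atruth.cells["barcode"], outdir / "whitelist.txt")
        else:
            cells_to_annotation(atruth.cells).to_tsv(outdir / "atac_cells.tsv")
        with open(outdir / "truth_access.tsv", "w") as fh:
            fh.write("peak_index\tgroup_A\tgroup_B\teffect\n")
            for i in range(n_peaks):
                fh.write(
                    f"{i}\t{access['A'][i]:.6f}\t{access['B'][i]:.6f}\t{int(effect_mask[i])}\n"
                )
        manifest["n_peaks"] = n_peaks
        manifest["n_fragments"] = len(frags)

    return manifest
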