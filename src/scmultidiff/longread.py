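"""From aligned barcoded long reads to deduplicated, gene-assigned molecules
and per-molecule exon inclusion/exclusion calls.

A read becomes a molecule only after (i) its cell-barcode candidate matches a
whitelist entry exactly (conservative calling; an optional one-mismatch rescue
exists but is off by default), (ii) it is assigned to a unique gene by aligned
base overlap, and (iii) reads of the same cell and gene whose 10-mer UMI
candidates lie within Levenshtein distance < 4 of each other are collapsed
into one molecule. Two UMIs at edit distance >= 4 are distinct molecules.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib

from .core_io import GeneCollection, GenomicInterval, _maybe_gzip

UMI_LENGTH = 10
#: UMIs at Levenshtein distance >= this are distinct molecules.
MIN_UMI_DISTANCE = 4


@dataclass(frozen=True)
class LongReadRecord:
    """One aligned long read: barcode/UMI candidates plus aligned blocks.

    Gaps between consecutive blocks are introns spliced out of the molecule.
    """

    read_id: str
    barcode_candidate: str
    umi_candidate: str
    chrom: str
    strand: str
    blocks: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"read strand must be + or -, got {self.strand!r}")
        prev_end = None
        for b in self.blocks:
            if b.chrom != self.chrom:
                raise ValueError(f"block {b} not on read chromosome {self.chrom}")
            if prev_end is not None and b.start < prev_end:
                raise ValueError("read blocks must be sorted and non-overlapping")
            prev_end = b.end

    @property
    def aligned_bases(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.blocks[0].start, self.blocks[-1].end, self.strand
        )


@dataclass(frozen=True)
class Molecule:
    """A deduplicated cDNA molecule (one UMI cluster of one cell x gene)."""

    barcode: str
    umi: str
    gene_id: str
    chrom: str
    strand: str
    blocks: tuple[GenomicInterval, ...]
    n_reads: int = 1

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


class ExonStatus(str, Enum):
    INCLUSION = "inclusion"
    EXCLUSION = "exclusion"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class ExonCall:
    molecule: Molecule
    exon: GenomicInterval
    status: ExonStatus


def match_barcode(
    candidate: str, whitelist: frozenset | set, max_mismatch: int = 0
) -> str | None:
    """Whitelist-match a barcode candidate.

    Default is exact-only (conservative). With ``max_mismatch=1`` a candidate
    is rescued when exactly one whitelist entry is within Hamming distance 1.
    """
    if not candidate:
        return None
    if candidate in whitelist:
        return candidate
    if max_mismatch >= 1:
        hits = [
            w
            for w in whitelist
            if len(w) == len(candidate)
            and sum(a != b for a, b in zip(w, candidate)) == 1
        ]
        if len(hits) == 1:
            return hits[0]
    return None


def assign_gene(
    read: LongReadRecord,
    genes: GeneCollection,
    min_overlap_frac: float = 0.8,
    ambiguity_margin: float = 0.05,
) -> str | None:
    """Assign a read to the unique gene covering most of its aligned bases.

    A gene qualifies when it lies on the read's strand and its body contains at
    least ``min_overlap_frac`` of the read's aligned bases; if the runner-up
    gene's overlap fraction is within ``ambiguity_margin`` of the best, the
    read is ambiguous and unassigned.
    """
    total = read.aligned_bases
    if total == 0:
        return None
    span = read.span
    fracs: list[tuple[float, str]] = []
    for gene in genes.overlapping(span.chrom, span.start, span.end):
        if gene.interval.strand in ("+", "-") and gene.interval.strand != read.strand:
            continue
        ov = sum(b.overlap_len(gene.interval) for b in read.blocks)
        if ov > 0:
            fracs.append((ov / total, gene.gene_id))
    if not fracs:
        return None
    fracs.sort(key=lambda t: (-t[0], t[1]))
    best_frac, best_gene = fracs[0]
    if best_frac < min_overlap_frac:
        return None
    if len(fracs) > 1 and fracs[1][0] >= best_frac - ambiguity_margin:
        return None
    return best_gene


def edit_distance(a: str, b: str, mode: str = "levenshtein") -> int:
    """Levenshtein (default) or Hamming distance between two UMI strings."""
    if mode == "levenshtein":
        return edlib.align(a, b, task="distance")["editDistance"]
    if mode == "hamming":
        if len(a) != len(b):
            raise ValueError("hamming mode requires equal-length strings")
        return sum(x != y for x, y in zip(a, b))
    raise ValueError(f"unknown edit-distance mode {mode!r}")


def dedup_umis(
    reads: Sequence[LongReadRecord],
    barcode: str,
    gene_id: str,
    min_distance: int = MIN_UMI_DISTANCE,
    mode: str = "levenshtein",
) -> list[Molecule]:
    """Collapse reads of one (barcode, gene) into molecules by UMI clustering.

    Single-linkage clustering over the graph with an edge between two reads
    whenever their UMI candidates are at edit distance < ``min_distance``.
    Each cluster's representative UMI is the candidate supported by most reads
    (ties: lexicographically smallest); representative blocks are those of the
    longest read (most aligned bases; ties: smallest read_id). Output order is
    independent of input order.
    """
    if not reads:
        return []
    for r in reads:
        if len(r.umi_candidate) != UMI_LENGTH:
            raise ValueError(
                f"UMI candidate {r.umi_candidate!r} of read {r.read_id} is not "
                f"{UMI_LENGTH} nt"
            )
    ordered = sorted(reads, key=lambda r: (r.umi_candidate, r.read_id))
    parent = list(range(len(ordered)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(ordered)), 2):
        if edit_distance(ordered[i].umi_candidate, ordered[j].umi_candidate, mode) < min_distance:
            parent[find(i)] = find(j)

    clusters: dict[int, list[LongReadRecord]] = {}
    for i in range(len(ordered)):
        clusters.setdefault(find(i), []).append(ordered[i])

    molecules = []
    for members in clusters.values():
        umi_counts = Counter(r.umi_candidate for r in members)
        top = max(umi_counts.values())
        umi = min(u for u, n in umi_counts.items() if n == top)
        rep = max(members, key=lambda r: (r.aligned_bases, r.read_id))
        molecules.append(
            Molecule(
                barcode=barcode,
                umi=umi,
                gene_id=gene_id,
                chrom=rep.chrom,
                strand=rep.strand,
                blocks=rep.blocks,
                n_reads=len(members),
            )
        )
    molecules.sort(key=lambda m: (m.umi, m.blocks[0].start))
    return molecules


@dataclass
class MoleculeExtractionStats:
    n_reads: int = 0
    n_barcode_unmatched: int = 0
    n_gene_unassigned: int = 0
    n_molecules: int = 0


def extract_molecules(
    reads: Iterable[LongReadRecord],
    whitelist: set | frozenset,
    genes: GeneCollection,
    min_overlap_frac: float = 0.8,
    ambiguity_margin: float = 0.05,
    barcode_max_mismatch: int = 0,
    umi_min_distance: int = MIN_UMI_DISTANCE,
) -> tuple[list[Molecule], MoleculeExtractionStats]:
    """Full read -> molecule pipeline: barcode match, gene assignment, UMI dedup."""
    stats = MoleculeExtractionStats()
    groups: dict[tuple[str, str], list[LongReadRecord]] = {}
    whitelist = frozenset(whitelist)
    for read in reads:
        stats.n_reads += 1
        bc = match_barcode(read.barcode_candidate, whitelist, barcode_max_mismatch)
        if bc is None:
            stats.n_barcode_unmatched += 1
            continue
        gene = assign_gene(read, genes, min_overlap_frac, ambiguity_margin)
        if gene is None:
            stats.n_gene_unassigned += 1
            continue
        groups.setdefault((bc, gene), []).append(read)
    molecules: list[Molecule] = []
    for (bc, gene) in sorted(groups):
        molecules.extend(
            dedup_umis(groups[(bc, gene)], bc, gene, min_distance=umi_min_distance)
        )
    stats.n_molecules = len(molecules)
    return molecules, stats


def call_exon(
    molecule: Molecule | Sequence[GenomicInterval],
    exon: GenomicInterval,
    tol: int = 0,
) -> ExonStatus:
    """Classify one molecule as including, excluding, or uninformative for an exon.

    Inclusion: an internal block (spliced on both sides) whose boundaries match
    the exon's start and end within +-tol. Exclusion: an inter-block gap
    (intron) fully contains the exon. Anything else — reads ending inside the
    exon or its flanking introns, partial overlaps — is uninformative, which is
    conservative by construction. Strand is ignored given identical blocks.
    """
    blocks = molecule.blocks if isinstance(molecule, Molecule) else tuple(molecule)
    chrom = blocks[0].chrom if blocks else None
    if not blocks or chrom != exon.chrom:
        return ExonStatus.UNINFORMATIVE
    for i in range(1, len(blocks) - 1):
        b = blocks[i]
        if abs(b.start - exon.start) <= tol and abs(b.end - exon.end) <= tol:
            return ExonStatus.INCLUSION
    for left, right in zip(blocks, blocks[1:]):
        if left.end <= exon.start and exon.end <= right.start:
            return ExonStatus.EXCLUSION
    return ExonStatus.UNINFORMATIVE


def call_exons(
    molecules: Iterable[Molecule],
    exons_by_gene: Mapping[str, Sequence[GenomicInterval]],
    tol: int = 0,
    keep_uninformative: bool = False,
) -> list[ExonCall]:
    """Call every exon of each molecule's gene against that molecule."""
    calls = []
    for mol in molecules:
        for exon in exons_by_gene.get(mol.gene_id, ()):
            status = call_exon(mol, exon, tol)
            if status is not ExonStatus.UNINFORMATIVE or keep_uninformative:
                calls.append(ExonCall(mol, exon, status))
    return calls


def build_inclusion_table(
    calls: Iterable[ExonCall],
    barcode_to_group: Mapping[str, str],
):
    """Aggregate molecule-level calls into per-(exon, group) inclusion counts.

    Calls whose barcode does not resolve to a group are dropped (and counted);
    uninformative calls never enter the table. Returns (table, n_dropped).
    """
    from .splice_diff import ExonInclusionTable

    table = ExonInclusionTable()
    n_dropped = 0
    for call in calls:
        if call.status is ExonStatus.UNINFORMATIVE:
            continue
        group = barcode_to_group.get(call.molecule.barcode)
        if group is None:
            n_dropped += 1
            continue
        table.add(
            call.molecule.gene_id,
            call.exon,
            group,
            inc=int(call.status is ExonStatus.INCLUSION),
            exc=int(call.status is ExonStatus.EXCLUSION),
        )
    return table, n_dropped


@dataclass
class CoinclusionResult:
    """Molecule-level association between two exons of one gene.

    ``table`` rows are exon-1 {inclusion, exclusion}, columns exon-2
    {inclusion, exclusion}; a phi of +1 means the two exons are always
    included or excluded from the same individual molecules (coordinated
    splicing), -1 perfect anti-coordination.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    phi: float
    n_molecules: int


def coinclusion_association(
    statuses: Iterable[tuple[ExonStatus, ExonStatus]],
) -> CoinclusionResult | None:
    """Pairwise exon co-inclusion across molecules informative for both exons."""
    import math

    from scipy.stats import fisher_exact

    a = b = c = d = 0  # [inc,inc], [inc,exc], [exc,inc], [exc,exc]
    for s1, s2 in statuses:
        if ExonStatus.UNINFORMATIVE in (s1, s2):
            continue
        if s1 is ExonStatus.INCLUSION:
            if s2 is ExonStatus.INCLUSION:
                a += 1
            else:
                b += 1
        else:
            if s2 is ExonStatus.INCLUSION:
                c += 1
            else:
                d += 1
    n = a + b + c + d
    if n < 1:
        return None
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    denom = math.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    phi = (a * d - b * c) / denom if denom > 0 else 0.0
    return CoinclusionResult(((a, b), (c, d)), float(p), phi, n)


def read_bed12(
    path: str | Path,
    sidecar: str | Path | None = None,
    name_delim: str | None = None,
) -> list[LongReadRecord]:
    """Read aligned long reads from BED12 (one read per line, blocks from
    blockSizes/blockStarts).

    Barcode and UMI come either from the read name split on ``name_delim``
    (read_id<delim>barcode<delim>umi) or from a sidecar TSV with columns
    read_id, barcode, umi.
    """
    meta: dict[str, tuple[str, str]] = {}
    if sidecar is not None:
        with _maybe_gzip(sidecar) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for col in ("read_id", "barcode", "umi"):
                if col not in idx:
                    raise ValueError(f"{sidecar}: missing column {col!r}")
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                meta[fields[idx["read_id"]]] = (
                    fields[idx["barcode"]],
                    fields[idx["umi"]],
                )

    reads: list[LongReadRecord] = []
    with _maybe_gzip(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}: BED12 line {lineno}: expected 12 columns")
            chrom, chrom_start, name, strand = (
                fields[0],
                int(fields[1]),
                fields[3],
                fields[5],
            )
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            blocks = tuple(
                GenomicInterval(chrom, chrom_start + s, chrom_start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            )
            if name_delim is not None:
                read_id, barcode, umi = name.split(name_delim)[:3]
            elif name in meta:
                read_id = name
                barcode, umi = meta[name]
            else:
                raise ValueError(
                    f"{path}: line {lineno}: read {name!r} has no barcode/UMI "
                    "(provide a sidecar TSV or a name delimiter)"
                )
            reads.append(LongReadRecord(read_id, barcode, umi, chrom, strand, blocks))
    return reads


def write_bed12(reads: Iterable[LongReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            start = r.blocks[0].start
            end = r.blocks[-1].end
            sizes = ",".join(str(len(b)) for b in r.blocks)
            starts = ",".join(str(b.start - start) for b in r.blocks)
            fh.write(
                f"{r.chrom}\t{start}\t{end}\t{r.read_id}\t0\t{r.strand}\t{start}\t{end}"
                f"\t0\t{len(r.blocks)}\t{sizes}\t{starts}\n"
            )


def write_read_sidecar(reads: Iterable[LongReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tbarcode\tumi\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.barcode_candidate}\t{r.umi_candidate}\n")


def write_molecules(molecules: Iterable[Molecule], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("barcode\tumi\tgene_id\tchrom\tstrand\tn_reads\tblocks\n")
        for m in molecules:
            blocks = ";".join(f"{b.start}-{b.end}" for b in m.blocks)
            fh.write(
                f"{m.barcode}\t{m.umi}\t{m.gene_id}\t{m.chrom}\t{m.strand}\t{m.n_reads}\t{blocks}\n"
            )
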