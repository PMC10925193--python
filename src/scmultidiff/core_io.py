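"""Domain types and readers/writers for the genomic formats the pipeline touches.

Every coordinate held in memory is 0-based, half-open. Conversion to and from
external conventions happens only here: GTF is 1-based inclusive; BED and the
10x-style fragments dialect are already 0-based half-open. Chromosome-name
dialects ("chr1" vs "1") are never translated silently; callers may pass an
explicit alias table where a reader supports one.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and max(self.start, other.start) < min(
            self.end, other.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between two intervals on the same chromosome (0 if they
        overlap or abut); None for different chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union overlapping/abutting intervals per chromosome; strand is dropped."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[GenomicInterval] = field(default_factory=list)
    utrs: list[GenomicInterval] = field(default_factory=list)

    def sort(self) -> None:
        self.exons.sort(key=lambda e: (e.start, e.end))
        self.utrs.sort(key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}: {a} / {b}"
                )


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    interval: GenomicInterval
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def exons(self) -> list[GenomicInterval]:
        """Distinct exon intervals across all transcripts, sorted."""
        seen = {(e.start, e.end): e for t in self.transcripts for e in t.exons}
        return [seen[k] for k in sorted(seen)]

    @property
    def utrs(self) -> list[GenomicInterval]:
        seen = {(u.start, u.end): u for t in self.transcripts for u in t.utrs}
        return [seen[k] for k in sorted(seen)]

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand != "-" else self.interval.end

    def alternative_internal_exons(self) -> list[GenomicInterval]:
        """Exons that are internal in some transcript but absent from at least
        one other transcript of the gene — the annotated skippable exons."""
        if len(self.transcripts) < 2:
            return []
        internal: set[tuple[int, int]] = set()
        for t in self.transcripts:
            for e in t.exons[1:-1]:
                internal.add((e.start, e.end))
        out = []
        for s, e in sorted(internal):
            iv = GenomicInterval(self.interval.chrom, s, e, self.interval.strand)
            n_with = sum(
                any(x.start == s and x.end == e for x in t.exons)
                for t in self.transcripts
            )
            if n_with < len(self.transcripts):
                out.append(iv)
        return out


class GeneCollection:
    """Gene models indexed by id, name, and genomic position."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        self._by_name: dict[str, list[GeneModel]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self._genes[g.gene_id] = g
            self._by_name.setdefault(g.gene_name, []).append(g)
            self._trees.setdefault(g.interval.chrom, IntervalTree()).addi(
                g.interval.start, g.interval.end, g.gene_id
            )

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def get(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def by_name(self, name: str) -> list[GeneModel]:
        return self._by_name.get(name, [])

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(start, end), key=lambda h: (h.begin, h.end, h.data))
        return [self._genes[h.data] for h in hits]

    def chroms(self) -> list[str]:
        return sorted(self._trees)


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_UTR_FEATURES = {"UTR", "five_prime_utr", "three_prime_utr", "5UTR", "3UTR"}


def read_gtf(path: str | Path) -> GeneCollection:
    """Parse a GTF into gene models (coordinates converted to 0-based half-open).

    Only ``exon`` and UTR features are used; the gene interval is the span of a
    gene's exons unless an explicit ``gene`` feature line is present.
    """
    genes: dict[str, dict] = {}
    with _maybe_gzip(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: expected 9 fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature not in ("exon", "gene") and feature not in _UTR_FEATURES:
                continue
            try:
                start = int(start_s) - 1  # 1-based inclusive -> 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: non-integer coordinates"
                ) from exc
            attrs = dict(_GTF_ATTR_RE.findall(attrs_s))
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise ValueError(f"{path}: GTF line {lineno}: missing gene_id attribute")
            rec = genes.setdefault(
                gene_id,
                {
                    "name": attrs.get("gene_name", gene_id),
                    "chrom": chrom,
                    "strand": strand if strand in ("+", "-") else ".",
                    "span": None,
                    "transcripts": {},
                },
            )
            if rec["chrom"] != chrom:
                raise ValueError(
                    f"{path}: GTF line {lineno}: gene {gene_id} spans chromosomes"
                )
            if feature == "gene":
                rec["span"] = (start, end)
                continue
            tx_id = attrs.get("transcript_id")
            if not tx_id:
                raise ValueError(
                    f"{path}: GTF line {lineno}: missing transcript_id attribute"
                )
            tx = rec["transcripts"].setdefault(tx_id, TranscriptModel(tx_id))
            iv = GenomicInterval(chrom, start, end, rec["strand"])
            if feature == "exon":
                tx.exons.append(iv)
            else:
                tx.utrs.append(iv)

    models = []
    for gene_id, rec in genes.items():
        transcripts = list(rec["transcripts"].values())
        for t in transcripts:
            t.sort()
        all_exons = [e for t in transcripts for e in t.exons]
        if rec["span"] is not None:
            span = rec["span"]
        elif all_exons:
            span = (min(e.start for e in all_exons), max(e.end for e in all_exons))
        else:
            continue
        interval = GenomicInterval(rec["chrom"], span[0], span[1], rec["strand"])
        models.append(GeneModel(gene_id, rec["name"], interval, transcripts))
    return GeneCollection(models)


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Emit gene/exon (and UTR) features; 0-based half-open -> 1-based inclusive."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write(
                f"{iv.chrom}\tscmultidiff\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                tattrs = attrs + f' transcript_id "{t.transcript_id}";'
                for e in t.exons:
                    fh.write(
                        f"{e.chrom}\tscmultidiff\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{tattrs}\n"
                    )
                for u in t.utrs:
                    fh.write(
                        f"{u.chrom}\tscmultidiff\tUTR\t{u.start + 1}\t{u.end}\t.\t{u.strand}\t.\t{tattrs}\n"
                    )


@dataclass(frozen=True)
class FragmentRecord:
    """One scATAC fragment: Tn5 insertion interval + cell barcode + duplicate count."""

    interval: GenomicInterval
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("fragment count must be >= 1")


def read_fragments(path: str | Path) -> tuple[list[FragmentRecord], int]:
    """Read a 10x-dialect fragments TSV (plain or gzipped).

    Columns: chrom, start, end, barcode, count; '#' header lines are skipped;
    coordinates are taken as already 0-based half-open. Returns the records in
    file order plus the number of rejected (start >= end) lines.
    """
    records: list[FragmentRecord] = []
    n_rejected = 0
    with _maybe_gzip(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"{path}: fragments line {lineno}: expected >=5 columns"
                )
            chrom, start_s, end_s, barcode, count_s = fields[:5]
            try:
                start, end, count = int(start_s), int(end_s), int(count_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: fragments line {lineno}: non-integer field"
                ) from exc
            if start >= end:
                logger.warning(
                    "%s line %d: rejected fragment with start >= end", path, lineno
                )
                n_rejected += 1
                continue
            records.append(
                FragmentRecord(GenomicInterval(chrom, start, end), barcode, count)
            )
    return records, n_rejected


def write_fragments(records: Iterable[FragmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t{r.barcode}\t{r.count}\n"
            )


@dataclass(frozen=True)
class CellAnnotation:
    barcode: str
    sample_id: str
    cell_type: str
    subtype: str
    condition: str


REQUIRED_CELL_COLUMNS = ("barcode", "sample", "cell_type", "subtype", "condition")


class CellAnnotationTable:
    """Cell annotations queryable by (cell_type or subtype) x condition.

    The condition column carries whatever two-level contrast a comparison uses
    (brain region, species, diagnosis, ...); to this table it is an opaque label.
    """

    def __init__(self, cells: Iterable[CellAnnotation]):
        self.cells = list(cells)
        seen: set[tuple[str, str]] = set()
        for c in self.cells:
            key = (c.barcode, c.sample_id)
            if key in seen:
                raise ValueError(
                    f"duplicate (barcode, sample) pair {key} in cell annotations"
                )
            seen.add(key)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CellAnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in REQUIRED_CELL_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        return cls(
            CellAnnotation(r.barcode, r.sample, r.cell_type, r.subtype, r.condition)
            for r in df.itertuples()
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(REQUIRED_CELL_COLUMNS) + "\n")
            for c in self.cells:
                fh.write(
                    f"{c.barcode}\t{c.sample_id}\t{c.cell_type}\t{c.subtype}\t{c.condition}\n"
                )

    def __len__(self) -> int:
        return len(self.cells)

    def conditions(self) -> list[str]:
        return sorted({c.condition for c in self.cells})

    def barcodes(
        self,
        cell_type: str | None = None,
        subtype: str | None = None,
        condition: str | None = None,
    ) -> set[str]:
        out = set()
        for c in self.cells:
            if cell_type is not None and c.cell_type != cell_type:
                continue
            if subtype is not None and (not c.subtype or c.subtype != subtype):
                continue
            if condition is not None and c.condition != condition:
                continue
            out.add(c.barcode)
        return out

    def barcode_to_group(
        self,
        level: str = "condition",
        cell_type: str | None = None,
        subtype: str | None = None,
    ) -> dict[str, str]:
        """Map barcode -> group label for a comparison.

        ``level`` names the column whose values are the group labels
        (condition, cell_type, or subtype); optional cell_type/subtype
        restrict which cells enter. Rows with an empty label at ``level``
        are excluded.
        """
        if level not in ("condition", "cell_type", "subtype"):
            raise ValueError(f"unknown grouping level {level!r}")
        mapping: dict[str, str] = {}
        for c in self.cells:
            if cell_type is not None and c.cell_type != cell_type:
                continue
            if subtype is not None and c.subtype != subtype:
                continue
            label = getattr(c, level)
            if not label:
                continue
            mapping[c.barcode] = label
        return mapping


def read_cell_annotations(path: str | Path) -> CellAnnotationTable:
    """Read the cell annotation TSV (barcode, sample, cell_type, subtype, condition)."""
    return CellAnnotationTable.from_tsv(path)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 (0-based half-open) into intervals (strand kept if present)."""
    out: list[GenomicInterval] = []
    with _maybe_gzip(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: BED line {lineno}: expected >=3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED3 (or BED6 when names/scores given), sorted by chrom then start."""
    rows = list(
        zip(
            intervals,
            names if names is not None else [None] * len(intervals),
            scores if scores is not None else [0] * len(intervals),
        )
    )
    rows.sort(key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    bed6 = names is not None or scores is not None
    with open(path, "w") as fh:
        for iv, name, score in rows:
            if bed6:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name or '.'}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_text_list(path: str | Path) -> list[str]:
    """One token per line (barcode whitelists, gene lists); blanks skipped."""
    with _maybe_gzip(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_text_list(items: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for item in items:
            fh.write(f"{item}\n")


def write_mtx(
    counts, barcodes: Sequence[str], peaks: Sequence[GenomicInterval], prefix: str | Path
) -> None:
    """Export a cells x peaks sparse matrix as Matrix Market plus sidecars."""
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    prefix = Path(prefix)
    mmwrite(str(prefix) + ".mtx", coo_matrix(counts))
    write_text_list(barcodes, str(prefix) + ".barcodes.txt")
    write_bed(list(peaks), str(prefix) + ".peaks.bed")


def _maybe_gzip(path: str | Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "r")
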