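"""Non-redundant lncRNA gene models from redundant transcript collections.

Public lncRNA catalogs list hundreds of thousands of partially overlapping
isoforms without grouping them into loci. This module collapses a
strand-aware transcript collection into putative functional units ("lncRNA
genes") in three passes:

1. two multiexonic-capable transcripts are grouped when their bodies
   overlap by >= 60% of the shorter transcript AND at least one exon pair
   shares >= 60% of the longer exon's coordinates; groups are the
   single-linkage transitive closure of this relation;
2. remaining monoexonic transcripts are attached to a group when >= 30% of
   their genomic span overlaps the group's merged span;
3. remaining multiexonic transcripts are attached when >= 90% of their
   exonic bases fall inside the group's merged exons.

Upstream of clustering, exons poorly supported by read coverage are
removed, and regions overlapping protein-coding annotation (coding exons on
any strand, coding introns on the same strand) are excised, dropping
transcripts that lose more than 70% of their exonic bases.

All coordinates are 0-based half-open internally; GTF input/output converts
from/to the 1-based closed convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from . import intervals as iv
from .intervals import Interval


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TranscriptRecord:
    """One lncRNA isoform: ordered disjoint exons on one chromosome/strand."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    source: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript without exons")
        iv.validate(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    @property
    def exonic_bp(self) -> int:
        return iv.total_length(self.exons)

    @property
    def is_monoexonic(self) -> bool:
        return len(self.exons) == 1


@dataclass
class CodingAnnotation:
    """Protein-coding exons and introns, kept per strand.

    Introns are the gaps between consecutive exons of each coding
    transcript. Exon/intron interval lists are merged per (chrom, strand).
    """

    exons: dict[tuple[str, str], list[Interval]] = field(default_factory=dict)
    introns: dict[tuple[str, str], list[Interval]] = field(default_factory=dict)

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[TranscriptRecord]) -> "CodingAnnotation":
        exons: dict[tuple[str, str], list[Interval]] = {}
        introns: dict[tuple[str, str], list[Interval]] = {}
        for t in transcripts:
            key = (t.chrom, t.strand)
            exons.setdefault(key, []).extend(t.exons)
            for (_, left_end), (right_start, _) in zip(t.exons, t.exons[1:]):
                introns.setdefault(key, []).append((left_end, right_start))
        return cls(
            {k: iv.merge(v) for k, v in exons.items()},
            {k: iv.merge(v) for k, v in introns.items()},
        )

    def exons_any_strand(self, chrom: str) -> list[Interval]:
        out = []
        for strand in "+-":
            out.extend(self.exons.get((chrom, strand), []))
        return iv.merge(out)

    def introns_same_strand(self, chrom: str, strand: str) -> list[Interval]:
        return self.introns.get((chrom, strand), [])


@dataclass(frozen=True)
class LncRnaGene:
    """A merged functional unit built from one or more member transcripts."""

    gene_id: str
    chrom: str
    strand: str
    member_transcript_ids: tuple[str, ...]
    merged_exons: tuple[Interval, ...]

    @property
    def start(self) -> int:
        return self.merged_exons[0][0]

    @property
    def end(self) -> int:
        return self.merged_exons[-1][1]

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    @property
    def n_exons(self) -> int:
        return len(self.merged_exons)

    @property
    def complexity(self) -> int:
        return gene_complexity(self)


def gene_complexity(gene: LncRnaGene) -> int:
    """Structural complexity: number of merged exons times genomic span (bp).

    Gene length here is the genomic span (end - start), not the summed exon
    length, so a 148-exon, 150 kb gene scores 148 * 150,000.
    """
    return gene.n_exons * gene.span_bp


# ---------------------------------------------------------------------------
# parsing

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf(lines: Iterable[str]) -> list[TranscriptRecord]:
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    order: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationError(f"line {lineno}: expected 9 GTF fields, got {len(fields)}")
        chrom, source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        if feature != "exon":
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise AnnotationError(f"line {lineno}: non-integer coordinates") from None
        if end1 < start1:
            raise AnnotationError(f"line {lineno}: exon end {end1} < start {start1}")
        attr_map = dict(_GTF_ATTR_RE.findall(attrs))
        tid = attr_map.get("transcript_id")
        if tid is None:
            raise AnnotationError(f"line {lineno}: exon without transcript_id")
        # GTF is 1-based closed -> 0-based half-open
        exon = (start1 - 1, end1)
        if tid not in exons:
            exons[tid] = []
            meta[tid] = (chrom, strand, source)
            order.append(tid)
        elif meta[tid][0] != chrom or meta[tid][1] != strand:
            raise AnnotationError(f"line {lineno}: transcript {tid} mixes chromosome or strand")
        exons[tid].append(exon)
    records = []
    for tid in order:
        chrom, strand, source = meta[tid]
        records.append(
            TranscriptRecord(tid, chrom, strand, tuple(sorted(exons[tid])), source)
        )
    return records


def _parse_bed12(lines: Iterable[str]) -> list[TranscriptRecord]:
    records = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise AnnotationError(f"line {lineno}: expected 12 BED fields, got {len(fields)}")
        chrom = fields[0]
        try:
            chrom_start = int(fields[1])
            chrom_end = int(fields[2])
            block_count = int(fields[9])
            block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError:
            raise AnnotationError(f"line {lineno}: non-integer BED field") from None
        name, strand = fields[3], fields[5]
        if len(block_sizes) != block_count or len(block_starts) != block_count:
            raise AnnotationError(f"line {lineno}: blockCount mismatch")
        exons = []
        for size, off in zip(block_sizes, block_starts):
            s = chrom_start + off
            e = s + size
            if e > chrom_end:
                raise AnnotationError(f"line {lineno}: block extends past chromEnd")
            exons.append((s, e))
        records.append(TranscriptRecord(name, chrom, strand, tuple(sorted(exons)), "bed12"))
    return records


def parse_transcript_annotation(path, fmt: str | None = None) -> list[TranscriptRecord]:
    """Read a transcript annotation (GTF exon features or BED12).

    ``fmt`` is ``"gtf"`` or ``"bed12"``; inferred from the file suffix when
    omitted. Records are returned in input order; GTF coordinates are
    converted to the internal 0-based half-open convention.
    """
    path = str(path)
    if fmt is None:
        fmt = "bed12" if path.endswith((".bed", ".bed12")) else "gtf"
    with open(path) as fh:
        if fmt == "gtf":
            return _parse_gtf(fh)
        if fmt == "bed12":
            return _parse_bed12(fh)
    raise ValueError(f"unknown annotation format {fmt!r}")


def write_genes_bed12(genes: Sequence[LncRnaGene], path) -> None:
    """Write merged genes as BED12, one line per gene (blocks = merged exons)."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.merged_exons)
            offs = ",".join(str(s - g.start) for s, _ in g.merged_exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        str(g.n_exons),
                        sizes,
                        offs,
                    ]
                )
                + "\n"
            )


def write_membership_tsv(genes: Sequence[LncRnaGene], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_id\n")
        for g in genes:
            for tid in g.member_transcript_ids:
                fh.write(f"{g.gene_id}\t{tid}\n")


# ---------------------------------------------------------------------------
# exon coverage filtering


def filter_uncovered_exons(
    transcripts: Sequence[TranscriptRecord],
    coverage: Mapping[tuple[str, int], float],
    min_covered_fraction: float = 0.10,
) -> tuple[list[TranscriptRecord], dict]:
    """Drop exons whose covered fraction falls below ``min_covered_fraction``.

    ``coverage`` maps ``(transcript_id, exon_index)`` to the fraction of
    exon bases covered by at least one read. The default keeps an exon
    unless >= 90% of its length is uncovered; pass 0.9 instead to require
    near-complete coverage. Transcripts losing all exons are dropped.

    Returns ``(surviving transcripts, report)`` where the report lists
    removed exons and dropped transcript ids.
    """
    missing = sorted(
        {
            t.transcript_id
            for t in transcripts
            for i in range(len(t.exons))
            if (t.transcript_id, i) not in coverage
        }
    )
    if missing:
        raise AnnotationError(
            "missing exon coverage records for transcripts: " + ", ".join(missing)
        )
    kept: list[TranscriptRecord] = []
    removed_exons: list[tuple[str, int, float]] = []
    dropped: list[str] = []
    for t in transcripts:
        surviving = []
        for i, exon in enumerate(t.exons):
            frac = coverage[(t.transcript_id, i)]
            if not 0.0 <= frac <= 1.0:
                raise AnnotationError(
                    f"{t.transcript_id} exon {i}: covered fraction {frac} outside [0, 1]"
                )
            if frac < min_covered_fraction:
                removed_exons.append((t.transcript_id, i, frac))
            else:
                surviving.append(exon)
        if surviving:
            kept.append(
                TranscriptRecord(t.transcript_id, t.chrom, t.strand, tuple(surviving), t.source)
            )
        else:
            dropped.append(t.transcript_id)
    return kept, {"removed_exons": removed_exons, "dropped_transcripts": dropped}


def read_exon_coverage_tsv(path) -> dict[tuple[str, int], float]:
    """Read a TSV of (transcript_id, exon_index, covered_fraction)."""
    cov: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("transcript_id"):
            raise AnnotationError("coverage TSV must start with a transcript_id header")
        for line in fh:
            tid, idx, frac = line.rstrip("\n").split("\t")
            cov[(tid, int(idx))] = float(frac)
    return cov


# ---------------------------------------------------------------------------
# coding-overlap subtraction


def subtract_coding_overlap(
    transcripts: Sequence[TranscriptRecord],
    coding: CodingAnnotation,
    max_loss_fraction: float = 0.70,
) -> tuple[list[TranscriptRecord], dict]:
    """Excise protein-coding overlap from lncRNA transcripts.

    Exonic bases overlapping coding exons (either strand) or coding introns
    (same strand only) are removed, splitting or trimming exons as needed.
    A transcript is dropped when the excised fraction of its exonic bases
    exceeds ``max_loss_fraction``.
    """
    kept: list[TranscriptRecord] = []
    dropped: list[tuple[str, float]] = []
    cache: dict[tuple[str, str], list[Interval]] = {}
    for t in transcripts:
        key = (t.chrom, t.strand)
        if key not in cache:
            cache[key] = iv.merge(
                list(coding.exons_any_strand(t.chrom))
                + list(coding.introns_same_strand(t.chrom, t.strand))
            )
        removal = cache[key]
        before = t.exonic_bp
        new_exons = iv.subtract(t.exons, removal)
        after = iv.total_length(new_exons)
        loss = 1.0 - after / before
        if loss > max_loss_fraction or not new_exons:
            dropped.append((t.transcript_id, loss))
        else:
            kept.append(
                TranscriptRecord(t.transcript_id, t.chrom, t.strand, tuple(new_exons), t.source)
            )
    return kept, {"dropped_transcripts": dropped}


# ---------------------------------------------------------------------------
# clustering


def _core_pair_rule(
    a: TranscriptRecord,
    b: TranscriptRecord,
    body_fraction: float,
    exon_fraction: float,
) -> bool:
    """Pass-1 grouping rule for a same-strand transcript pair."""
    body_ov = iv.overlap_length(a.span, b.span)
    if body_ov < body_fraction * min(a.span_bp, b.span_bp):
        return False
    for ea in a.exons:
        for eb in b.exons:
            ov = iv.overlap_length(ea, eb)
            longest = max(ea[1] - ea[0], eb[1] - eb[0])
            if ov >= exon_fraction * longest:
                return True
    return False


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _group_geometry(members: Sequence[TranscriptRecord]):
    merged = iv.merge([e for t in members for e in t.exons])
    return iv.span(merged), merged


def cluster_into_genes(
    transcripts: Sequence[TranscriptRecord],
    body_fraction: float = 0.60,
    exon_fraction: float = 0.60,
    mono_attach_fraction: float = 0.30,
    multi_attach_fraction: float = 0.90,
) -> list[LncRnaGene]:
    """Partition transcripts into lncRNA genes (see module docstring).

    Transcripts on opposite strands are never grouped. The result is a
    partition invariant to input order: pass-1 closure is single linkage,
    and pass-2/3 attachment is decided against a fixed snapshot of group
    geometry, attaching each transcript to the group with the largest
    base-pair overlap (ties to the leftmost group start); attachment never
    merges two groups.
    """
    order = sorted(
        range(len(transcripts)),
        key=lambda i: (
            transcripts[i].chrom,
            transcripts[i].strand,
            transcripts[i].start,
            transcripts[i].end,
            transcripts[i].transcript_id,
        ),
    )
    ts = [transcripts[i] for i in order]
    uf = _UnionFind(len(ts))

    # pass 1: pairwise core rule with single-linkage closure, per chrom/strand
    trees: dict[tuple[str, str], IntervalTree] = {}
    for i, t in enumerate(ts):
        key = (t.chrom, t.strand)
        tree = trees.setdefault(key, IntervalTree())
        for hit in tree.overlap(t.start, t.end):
            j = hit.data
            if _core_pair_rule(t, ts[j], body_fraction, exon_fraction):
                uf.union(i, j)
        tree.addi(t.start, t.end, i)

    components: dict[int, list[int]] = {}
    for i in range(len(ts)):
        components.setdefault(uf.find(i), []).append(i)
    groups = [sorted(v) for v in components.values()]
    multi_groups = [g for g in groups if len(g) > 1]
    singletons = [g[0] for g in groups if len(g) == 1]

    def attach_pass(candidates: list[int], monoexonic: bool) -> list[int]:
        """Attach qualifying singletons; return those left unattached."""
        geometry = [
            (_group_geometry([ts[i] for i in g]), ts[g[0]].chrom, ts[g[0]].strand)
            for g in multi_groups
        ]
        decisions: list[tuple[int, int]] = []
        left: list[int] = []
        for i in candidates:
            t = ts[i]
            best: tuple[int, int, int] | None = None  # (-overlap, group start, group idx)
            for gi, ((gspan, gexons), chrom, strand) in enumerate(geometry):
                if chrom != t.chrom or strand != t.strand:
                    continue
                if monoexonic:
                    ov = iv.overlap_length(t.span, gspan)
                    qualifies = ov >= mono_attach_fraction * t.span_bp
                else:
                    ov = iv.intersect_length(t.exons, gexons)
                    qualifies = ov >= multi_attach_fraction * t.exonic_bp
                if qualifies:
                    cand = (-ov, gspan[0], gi)
                    if best is None or cand < best:
                        best = cand
            if best is None:
                left.append(i)
            else:
                decisions.append((i, best[2]))
        for i, gi in decisions:
            multi_groups[gi].append(i)
        return left

    mono = [i for i in singletons if ts[i].is_monoexonic]
    multi = [i for i in singletons if not ts[i].is_monoexonic]
    left_mono = attach_pass(mono, monoexonic=True)
    left_multi = attach_pass(multi, monoexonic=False)

    final_groups = multi_groups + [[i] for i in left_mono + left_multi]
    genes = []
    for g in final_groups:
        members = sorted(
            (ts[i] for i in g), key=lambda t: (t.start, t.end, t.transcript_id)
        )
        gspan, merged = _group_geometry(members)
        chrom, strand = members[0].chrom, members[0].strand
        gene_id = f"{chrom}:{gspan[0]}-{gspan[1]}:{strand}"
        genes.append(
            LncRnaGene(
                gene_id,
                chrom,
                strand,
                tuple(t.transcript_id for t in members),
                tuple(merged),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.strand, g.end))
    return genes


def merge_pipeline(
    transcripts: Sequence[TranscriptRecord],
    coding: CodingAnnotation | None = None,
    coverage: Mapping[tuple[str, int], float] | None = None,
    min_covered_fraction: float = 0.10,
    max_loss_fraction: float = 0.70,
) -> tuple[list[LncRnaGene], dict]:
    """Full merge workflow: coverage filter, coding subtraction, clustering."""
    report: dict = {}
    if coverage is not None:
        transcripts, report["coverage"] = filter_uncovered_exons(
            transcripts, coverage, min_covered_fraction
        )
    if coding is not None:
        transcripts, report["coding"] = subtract_coding_overlap(
            transcripts, coding, max_loss_fraction
        )
    genes = cluster_into_genes(list(transcripts))
    return genes, report
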