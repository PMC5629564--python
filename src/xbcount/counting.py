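"""Read summarization over exonic, background and PRE/POST annotations.

Semantics follow the featureCounts defaults: a read (or properly paired
fragment, counted once) is assigned to a feature if any aligned base of any
of its CIGAR-match blocks overlaps the feature's exon union; reads touching
exons of more than one feature are discarded as ambiguous; unmapped,
secondary, supplementary and below-MAPQ alignments are skipped.

Coordinates are 0-based half-open internally; GTF is ingested as 1-based
inclusive, BED natively.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import NamedTuple

import pysam
from intervaltree import IntervalTree

from .apa import ApaCounts, ApaGeneGeometry

__all__ = [
    "GenomicInterval",
    "AnnotationParseError",
    "load_annotation",
    "CountResult",
    "count_reads",
    "count_apa",
    "load_apa_annotation",
]

logger = logging.getLogger(__name__)

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval carrying its feature ID."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    feature_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")


class AnnotationParseError(ValueError):
    pass


def _merge(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals of one feature on one chromosome."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start)):
        if out and iv.chrom == out[-1].chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(
                    iv.chrom, out[-1].start, iv.end, iv.strand, iv.feature_id
                )
        else:
            out.append(iv)
    return out


def load_annotation(path, format: str = "gtf") -> dict[str, list[GenomicInterval]]:
    """Load feature intervals grouped by feature ID, exon unions precomputed.

    ``format="gtf"``: exon records grouped by ``gene_id`` (1-based inclusive
    converted to 0-based half-open).  ``format="bed"``: BED4+/BED6, the name
    column is the feature ID, coordinates consumed natively.
    """
    if format not in ("gtf", "bed"):
        raise ValueError("format must be 'gtf' or 'bed'")
    feats: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "gtf":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated GTF fields")
                    if fields[2] != "exon":
                        continue
                    attrs = dict(_GTF_ATTR.findall(fields[8]))
                    fid = attrs["gene_id"]
                    iv = GenomicInterval(
                        fields[0], int(fields[3]) - 1, int(fields[4]), fields[6], fid
                    )
                else:
                    if len(fields) < 4:
                        raise ValueError("expected >= 4 BED columns (name required)")
                    fid = fields[3]
                    strand = fields[5] if len(fields) >= 6 else "+"
                    iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand, fid)
            except (ValueError, KeyError, IndexError) as exc:
                raise AnnotationParseError(f"{path}: line {lineno}: {exc}") from exc
            feats.setdefault(fid, []).append(iv)
    if not feats:
        logger.warning("%s: annotation is empty", path)
    return {fid: _merge(ivs) for fid, ivs in feats.items()}


def _build_trees(annotation: dict[str, list[GenomicInterval]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for fid, ivs in annotation.items():
        for iv in ivs:
            trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, (fid, iv.strand)
            )
    return trees


class CountResult(NamedTuple):
    counts: dict[str, int]
    ambiguous: int
    unassigned: int
    eligible: int


def _iter_fragments(aln: pysam.AlignmentFile, min_mapq: int):
    """Yield (blocks, strand, ref_name) per counting unit (read or fragment).

    Paired mates sharing a query name are buffered and emitted once with the
    union of both mates' aligned blocks; strand is read1's strand.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    for read in aln:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality < min_mapq:
            continue
        if read.is_paired:
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            r1, r2 = (read, mate) if read.is_read1 else (mate, read)
            blocks = [(r1.reference_name, b) for b in r1.get_blocks()] + [
                (r2.reference_name, b) for b in r2.get_blocks()
            ]
            yield blocks, ("-" if r1.is_reverse else "+")
        else:
            yield [(read.reference_name, b) for b in read.get_blocks()], (
                "-" if read.is_reverse else "+"
            )
    for read in pending.values():
        yield [(read.reference_name, b) for b in read.get_blocks()], (
            "-" if read.is_reverse else "+"
        )


def _overlapping_features(
    trees: dict[str, IntervalTree], blocks, read_strand: str, stranded: str
) -> set[str]:
    hits: set[str] = set()
    for chrom, (start, end) in blocks:
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.overlap(start, end):
            fid, fstrand = iv.data
            if stranded == "no":
                hits.add(fid)
            elif stranded == "forward" and fstrand == read_strand:
                hits.add(fid)
            elif stranded == "reverse" and fstrand != read_strand:
                hits.add(fid)
    return hits


def count_reads(
    alignments,
    annotation: dict[str, list[GenomicInterval]],
    stranded: str = "no",
    min_mapq: int = 0,
) -> CountResult:
    """Count reads/fragments per feature with featureCounts-default rules.

    ``alignments`` is a SAM/BAM path.  Returns per-feature counts plus the
    ambiguous/unassigned/eligible bookkeeping so that
    ``sum(counts) + ambiguous + unassigned == eligible``.
    """
    if stranded not in ("no", "forward", "reverse"):
        raise ValueError("stranded must be one of no/forward/reverse")
    trees = _build_trees(annotation)
    counts = {fid: 0 for fid in annotation}
    ambiguous = unassigned = eligible = 0
    try:
        aln = pysam.AlignmentFile(str(alignments), require_index=False)
    except (OSError, ValueError) as exc:
        raise OSError(
            f"{alignments}: not a readable SAM/BAM alignment file ({exc})"
        ) from exc
    with aln:
        for blocks, strand in _iter_fragments(aln, min_mapq):
            eligible += 1
            hits = _overlapping_features(trees, blocks, strand, stranded)
            if len(hits) == 1:
                counts[hits.pop()] += 1
            elif len(hits) > 1:
                ambiguous += 1
            else:
                unassigned += 1
    return CountResult(counts, ambiguous, unassigned, eligible)


def load_apa_annotation(
    path,
) -> tuple[dict[str, list[GenomicInterval]], dict[str, list[GenomicInterval]], dict[str, ApaGeneGeometry]]:
    """Load a PRE/POST BED annotation (name field ``geneID_PRE``/``geneID_POST``).

    Returns (pre intervals by gene, post intervals by gene, geometry by gene).
    Genes with a PRE but no POST record (or vice versa) are skipped with a
    warning.
    """
    raw = load_annotation(path, format="bed")
    pre: dict[str, list[GenomicInterval]] = {}
    post: dict[str, list[GenomicInterval]] = {}
    for fid, ivs in raw.items():
        if fid.endswith("_PRE"):
            pre[fid[: -len("_PRE")]] = ivs
        elif fid.endswith("_POST"):
            post[fid[: -len("_POST")]] = ivs
        else:
            raise AnnotationParseError(
                f"{path}: APA record name {fid!r} must end in _PRE or _POST"
            )
    geometry: dict[str, ApaGeneGeometry] = {}
    for gid in sorted(set(pre) | set(post)):
        if gid not in pre or gid not in post:
            logger.warning("APA gene %s lacks a paired PRE/POST record; skipped", gid)
            continue
        l_pre = sum(iv.end - iv.start for iv in pre[gid])
        l_post = sum(iv.end - iv.start for iv in post[gid])
        geometry[gid] = ApaGeneGeometry(
            gene_id=gid, l_pre=l_pre, l_post=l_post, strand=pre[gid][0].strand
        )
    pre = {g: pre[g] for g in geometry}
    post = {g: post[g] for g in geometry}
    return pre, post, geometry


def count_apa(
    alignments,
    apa_annotation,
    stranded: str = "no",
    min_mapq: int = 0,
) -> dict[str, ApaCounts]:
    """Per-gene (r_pre, r_post) from an alignment file and a PRE/POST BED.

    A read overlapping a gene's PRE region counts toward r_pre; a read
    overlapping only its POST extension counts toward r_post ("the portion
    only to the longer isoform").
    """
    if isinstance(apa_annotation, tuple):
        pre, post, geometry = apa_annotation
    else:
        pre, post, geometry = load_apa_annotation(apa_annotation)
    pre_trees = _build_trees({f"{g}": ivs for g, ivs in pre.items()})
    post_trees = _build_trees({f"{g}": ivs for g, ivs in post.items()})
    out = {g: [0, 0] for g in geometry}
    with pysam.AlignmentFile(str(alignments), require_index=False) as aln:
        for blocks, strand in _iter_fragments(aln, min_mapq):
            pre_hits = _overlapping_features(pre_trees, blocks, strand, stranded)
            post_hits = _overlapping_features(post_trees, blocks, strand, stranded)
            for g in pre_hits:
                out[g][0] += 1
            for g in post_hits - pre_hits:
                out[g][1] += 1
    return {g: ApaCounts(r_pre=v[0], r_post=v[1]) for g, v in out.items()}
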