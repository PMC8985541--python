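"""Classify spliced short-read alignments into per-intron junction evidence.

Evidence classes per intron (Fig.-style EE/EI strategy):

* ``EE``  — exon–exon junction read: an alignment N-gap matching the intron's
  (start, end) exactly, with >= ``min_overhang`` aligned nt on both sides.
* ``EI5`` — exon–intron read contiguously spanning the donor boundary.
* ``EI3`` — same at the acceptor boundary.
* ``IB``  — read aligned entirely within the intron body.

Also provides gene-level read counts / fpkm and the intergenic-background
expression threshold (95th percentile of intergenic-region fpkm).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree

from .genome_model import GeneModel, IntronRecord

DEFAULT_MIN_OVERHANG = 8

_SUPPORTED_OPS = {0, 1, 2, 3, 4, 5, 7, 8}  # M I D N S H = X


@dataclass
class JunctionCounts:
    sample_id: str
    intron_id: str
    EE: int = 0
    EI5: int = 0
    EI3: int = 0
    IB: int = 0
    sense_fraction: float = float("nan")


@dataclass
class GeneExpression:
    sample_id: str
    gene_id: str
    read_count: int
    fpkm: float


@dataclass
class BackgroundModel:
    sample_id: str
    intergenic_fpkm_quantile: float
    n_regions: int
    region_length: int
    percentile: float = 95.0
    interpolation: str = "linear"


def _open_alignments(alignments) -> pysam.AlignmentFile:
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments
    return pysam.AlignmentFile(str(alignments), check_sq=False)


def _blocks_and_gaps(read: pysam.AlignedSegment):
    """Aligned reference blocks (M/=/X/D contiguous) and N-gap intervals.

    Deletions keep a block contiguous: the read physically spans the
    reference there.  Returns None for unsupported CIGAR operations.
    """
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    pos = read.reference_start
    cur_start = pos
    has_block = False
    for op, length in read.cigartuples:
        if op not in _SUPPORTED_OPS:
            return None
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference
            pos += length
            has_block = True
        elif op == 3:  # N: splice gap
            if has_block:
                blocks.append((cur_start, pos))
            gaps.append((pos, pos + length))
            pos += length
            cur_start = pos
            has_block = False
        # I, S, H consume no reference
    if has_block:
        blocks.append((cur_start, pos))
    return blocks, gaps


def _read_is_sense(read: pysam.AlignedSegment, gene_strand: str, library_strand: str) -> bool:
    """Whether the read supports the annotated strand of its gene.

    ``forward``: read 1 (or a single-end read) maps on the gene strand;
    ``reverse``: the opposite (dUTP protocols).  Mates alternate.
    """
    read_strand = "-" if read.is_reverse else "+"
    expected = gene_strand
    if read.is_paired and read.is_read2:
        expected = "-" if expected == "+" else "+"
    if library_strand == "reverse":
        expected = "-" if expected == "+" else "+"
    return read_strand == expected


def count_junctions(
    alignments,
    introns: Sequence[IntronRecord],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    library_strand: str = "forward",
    sample_id: str | None = None,
    qc: dict | None = None,
) -> list[JunctionCounts]:
    """Count EE/EI5/EI3/IB evidence for every intron in one sample.

    A fragment (read pair) contributes at most once per category per intron;
    on conflicting mate assignments EE beats EI beats IB.  Reads failing the
    library-strand expectation enter the sense_fraction denominator but are
    excluded from the counts (unless ``library_strand == "unstranded"``).
    """
    if library_strand not in ("forward", "reverse", "unstranded"):
        raise ValueError(f"unknown library_strand: {library_strand}")
    af = _open_alignments(alignments)
    sample = sample_id or os.path.basename(str(getattr(af, "filename", b"sample").decode()
                                               if isinstance(getattr(af, "filename", ""), bytes)
                                               else getattr(af, "filename", "sample")))
    qc = qc if qc is not None else {}
    qc.setdefault("skipped_unmapped_or_secondary", 0)
    qc.setdefault("skipped_unsupported_cigar", 0)

    gap_index: dict[tuple[str, int, int], IntronRecord] = {}
    trees: dict[str, IntervalTree] = {}
    for intr in introns:
        gap_index[(intr.chrom, intr.start, intr.end)] = intr
        trees.setdefault(intr.chrom, IntervalTree()).addi(
            intr.start - min_overhang, intr.end + min_overhang, intr
        )

    # (qname, intron_id) -> [set of categories, all-reads-sense flag]
    frag: dict[tuple[str, str], list] = {}

    for read in af:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            qc["skipped_unmapped_or_secondary"] += 1
            continue
        bg = _blocks_and_gaps(read)
        if bg is None:
            qc["skipped_unsupported_cigar"] += 1
            continue
        blocks, gaps = bg
        chrom = read.reference_name
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = tree.overlap(read.reference_start, read.reference_end)
        if not hits:
            continue
        gapset = set(gaps)
        for h in hits:
            intr: IntronRecord = h.data
            cats = set()
            # EE: exact gap match with sufficient anchored overhang
            if (intr.start, intr.end) in gapset:
                gi = gaps.index((intr.start, intr.end))
                left = blocks[gi]
                right = blocks[gi + 1] if gi + 1 < len(blocks) else None
                if (
                    right is not None
                    and left[1] - left[0] >= min_overhang
                    and right[1] - right[0] >= min_overhang
                ):
                    cats.add("EE")
            # a read spliced at an alternative junction overlapping this
            # intron is not retention evidence: no EI/IB for it
            alt_spliced = any(
                gs < intr.end + min_overhang and ge > intr.start - min_overhang
                for gs, ge in gaps
                if (gs, ge) != (intr.start, intr.end)
            )
            # EI: a single block contiguously covering the boundary window
            if intr.strand == "+":
                d_win = (intr.start - min_overhang, intr.start + min_overhang)
                a_win = (intr.end - min_overhang, intr.end + min_overhang)
            else:
                d_win = (intr.end - min_overhang, intr.end + min_overhang)
                a_win = (intr.start - min_overhang, intr.start + min_overhang)
            for name, (ws, we) in (("EI5", d_win), ("EI3", a_win)):
                if not alt_spliced and any(
                    bs <= ws and we <= be for bs, be in blocks
                ):
                    cats.add(name)
            # IB: all aligned blocks inside the intron body
            if (
                not alt_spliced
                and blocks
                and all(intr.start <= bs and be <= intr.end for bs, be in blocks)
            ):
                cats.add("IB")
            if not cats:
                continue
            sense = _read_is_sense(read, intr.strand, library_strand)
            key = (read.query_name, intr.intron_id)
            entry = frag.setdefault(key, [set(), True])
            entry[0] |= cats
            entry[1] = entry[1] and sense

    by_intron: dict[str, JunctionCounts] = {
        i.intron_id: JunctionCounts(sample, i.intron_id) for i in introns
    }
    sense_n: dict[str, list[int]] = {i.intron_id: [0, 0] for i in introns}
    for (qname, iid), (cats, sense) in frag.items():
        if "EE" in cats:
            cats = {"EE"}
        elif cats & {"EI5", "EI3"}:
            cats = cats & {"EI5", "EI3"}
        counts = by_intron[iid]
        tally = sense_n[iid]
        tally[1] += 1
        if sense:
            tally[0] += 1
        if not sense and library_strand != "unstranded":
            continue
        for c in cats:
            setattr(counts, c, getattr(counts, c) + 1)
    for iid, (ns, nt) in sense_n.items():
        if nt:
            by_intron[iid].sense_fraction = ns / nt
    return [by_intron[i.intron_id] for i in introns]


def _count_mapped_fragments(af: pysam.AlignmentFile) -> tuple[int, list]:
    """Primary mapped fragments and their (chrom, start, end, strand, qname)."""
    recs = []
    for read in af:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.is_paired and read.is_read2:
            continue  # a pair counts as one fragment; mate 1 represents it
        recs.append(
            (
                read.reference_name,
                read.reference_start,
                read.reference_end,
                "-" if read.is_reverse else "+",
                read.is_paired,
                read.is_read2,
            )
        )
    return len(recs), recs


def compute_fpkm(
    alignments,
    genes: Sequence[GeneModel],
    library_strand: str = "forward",
    sample_id: str | None = None,
) -> list[GeneExpression]:
    """Gene read counts and fpkm over the exonic union, on the expected strand."""
    af = _open_alignments(alignments)
    sample = sample_id or "sample"
    total, recs = _count_mapped_fragments(af)
    if total == 0:
        raise ValueError(f"{sample}: zero mapped reads; sample unusable")

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        for s, e in g.exon_union():
            trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g)

    counts = {g.gene_id: 0 for g in genes}
    for chrom, start, end, strand, paired, _ in recs:
        tree = trees.get(chrom)
        if tree is None:
            continue
        seen = set()
        for h in tree.overlap(start, end):
            g: GeneModel = h.data
            if g.gene_id in seen:
                continue
            if library_strand != "unstranded":
                expected = g.strand
                if library_strand == "reverse":
                    expected = "-" if expected == "+" else "+"
                if strand != expected:
                    continue
            seen.add(g.gene_id)
            counts[g.gene_id] += 1

    mapped_millions = total / 1e6
    out = []
    for g in genes:
        kb = g.exonic_length() / 1000.0
        c = counts[g.gene_id]
        out.append(GeneExpression(sample, g.gene_id, c, c / (kb * mapped_millions)))
    return out


def background_threshold(
    alignments,
    genes: Sequence[GeneModel],
    n_regions: int = 500,
    region_length: int = 1000,
    seed: int = 0,
    flank: int = 1000,
    percentile: float = 95.0,
    sample_id: str | None = None,
) -> BackgroundModel:
    """Expression background: the 95th percentile of intergenic-region fpkm.

    Samples ``n_regions`` windows of ``region_length`` nt uniformly from the
    genome excluding gene spans +/- ``flank``, computes each window's fpkm,
    and returns the percentile with linear interpolation between order
    statistics (recorded in the output metadata).
    """
    af = _open_alignments(alignments)
    sample = sample_id or "sample"
    total, recs = _count_mapped_fragments(af)
    if total == 0:
        raise ValueError(f"{sample}: zero mapped reads; sample unusable")
    chrom_lengths = {af.get_reference_name(i): l for i, l in enumerate(af.lengths)}

    # allowed intervals = chromosome minus (gene span +/- flank), merged
    excl: dict[str, list[list[int]]] = {}
    for g in genes:
        excl.setdefault(g.chrom, []).append([g.tx_start - flank, g.tx_end + flank])
    allowed: list[tuple[str, int, int]] = []
    for chrom, clen in chrom_lengths.items():
        spans = sorted(excl.get(chrom, []))
        merged: list[list[int]] = []
        for s, e in spans:
            s = max(0, s)
            e = min(clen, e)
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        pos = 0
        for s, e in merged:
            if s - pos >= region_length:
                allowed.append((chrom, pos, s))
            pos = e
        if clen - pos >= region_length:
            allowed.append((chrom, pos, clen))

    weights = np.array([e - s - region_length + 1 for _, s, e in allowed], dtype=float)
    if len(allowed) == 0 or weights.sum() <= 0:
        raise ValueError(
            "genome too gene-dense to place intergenic regions; "
            "reduce n_regions or region_length"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(allowed), size=n_regions, p=weights / weights.sum())
    offsets = rng.random(n_regions)

    # per-chrom sorted fragment starts/ends for O(log n) overlap counting
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e, *_ in recs:
        per_chrom.setdefault(chrom, []).append((s, e))
    for chrom, ivs in per_chrom.items():
        arr = np.array(ivs)
        starts[chrom] = np.sort(arr[:, 0])
        ends[chrom] = np.sort(arr[:, 1])

    mapped_millions = total / 1e6
    kb = region_length / 1000.0
    values = np.empty(n_regions)
    for i, (k, off) in enumerate(zip(picks, offsets)):
        chrom, lo, hi = allowed[k]
        rs = lo + int(off * (hi - lo - region_length + 1))
        re_ = rs + region_length
        if chrom in starts:
            n = int(np.searchsorted(starts[chrom], re_, side="left")) - int(
                np.searchsorted(ends[chrom], rs, side="right")
            )
        else:
            n = 0
        values[i] = max(n, 0) / (kb * mapped_millions)
    # Weibull plotting positions: linear interpolation between order
    # statistics at rank q*(n+1), slightly conservative for sparse tails
    thr = float(np.percentile(values, percentile, method="weibull"))
    return BackgroundModel(
        sample, thr, n_regions, region_length, percentile, "weibull-linear"
    )


def counts_to_frame(counts: Iterable[JunctionCounts]):
    """JunctionCounts records as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "intron_id": c.intron_id,
                "EE": c.EE,
                "EI5": c.EI5,
                "EI3": c.EI3,
                "IB": c.IB,
                "sense_fraction": c.sense_fraction,
            }
            for c in counts
        ]
    )
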