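"""Targeted A-to-I editing quantification from aligned reads.

A-to-I editing reads out as A>G on the sense strand.  Given a small set of
labelled editing sites (the serotonin-receptor-2C exon Vb style A–E
cluster), this module tallies per-site editing fractions, per-read editing
haplotypes (the combination of edited sites on one molecule), and
alternative 5' splice-site usage (exon skipping), all from raw read
tallies with no amplification model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

DEFAULT_MIN_BASEQ = 20
DEFAULT_MIN_MAPQ = 20

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class EditingSiteSpec:
    site_label: str
    chrom: str
    position: int  # 0-based
    strand: str
    ref_base: str = "A"  # on the sense strand

    def __post_init__(self) -> None:
        if self.ref_base != "A":
            raise ValueError(
                f"site {self.site_label}: sense-strand reference base must be A"
            )


@dataclass
class SiteEditingResult:
    sample_id: str
    site_label: str
    n_ref: int
    n_edited: int
    n_other: int

    @property
    def editing_fraction(self) -> float:
        den = self.n_ref + self.n_edited
        return self.n_edited / den if den else float("nan")


@dataclass
class EditingHaplotypeTable:
    sample_id: str
    counts: dict[str, int]  # combination string ("" = unedited) -> reads

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percents(self) -> dict[str, float]:
        t = self.total
        return {k: 100.0 * v / t for k, v in self.counts.items()} if t else {}

    def marginal_fractions(self, labels: Sequence[str]) -> dict[str, float]:
        """Per-site edited fraction implied by the haplotype counts."""
        t = self.total
        return {
            lab: sum(v for k, v in self.counts.items() if lab in k) / t if t else float("nan")
            for lab in labels
        }


@dataclass
class SkippingResult:
    sample_id: str
    n_inclusion_junctions: int
    n_skipping_junctions: int

    @property
    def skipping_fraction(self) -> float:
        den = self.n_inclusion_junctions + self.n_skipping_junctions
        return self.n_skipping_junctions / den if den else float("nan")


def _open(alignments) -> pysam.AlignmentFile:
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments
    return pysam.AlignmentFile(str(alignments), check_sq=False)


def load_site_specs(path) -> list[EditingSiteSpec]:
    """Read a BED-like TSV: chrom, 0-based position, strand, label."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos, strand, label = line.split()[:4]
            sites.append(EditingSiteSpec(label, chrom, int(pos), strand))
    labels = [s.site_label for s in sites]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate site labels in spec")
    return sites


def _read_site_calls(
    read: pysam.AlignedSegment,
    sites: Sequence[EditingSiteSpec],
    min_baseq: int,
) -> dict[str, str | None]:
    """Per-site classification of one read: 'ref', 'edited', 'other' or None.

    For minus-strand sites the observed base is complemented first, so
    classification always happens in sense-transcript space (A = unedited,
    G = edited).
    """
    wanted = {
        s.position: s
        for s in sites
        if s.chrom == read.reference_name
        and read.reference_start <= s.position < (read.reference_end or 0)
    }
    out: dict[str, str | None] = {}
    if not wanted:
        return out
    quals = read.query_qualities
    seq = read.query_sequence
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        site = wanted.get(rpos)
        if site is None:
            continue
        if quals is not None and quals[qpos] < min_baseq:
            out[site.site_label] = None
            continue
        base = seq[qpos].upper()
        if site.strand == "-":
            base = _COMPLEMENT.get(base, "N")
        if base == "A":
            out[site.site_label] = "ref"
        elif base == "G":
            out[site.site_label] = "edited"
        else:
            out[site.site_label] = "other"
    return out


def site_editing(
    alignments,
    sites: Sequence[EditingSiteSpec],
    min_baseq: int = DEFAULT_MIN_BASEQ,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    sample_id: str = "sample",
    require_all_sites: bool = False,
) -> list[SiteEditingResult]:
    """Per-site editing tallies via an internal pileup over primary reads.

    With ``require_all_sites`` only reads covering every site with a
    passing base call contribute — the informative subset used for
    haplotype analysis, on which haplotype marginals equal these fractions
    exactly.
    """
    af = _open(alignments)
    labels = [s.site_label for s in sites]
    tallies = {lab: [0, 0, 0] for lab in labels}  # ref, edited, other
    for read in af:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality < min_mapq:
            continue
        calls = _read_site_calls(read, sites, min_baseq)
        if require_all_sites:
            # same informative subset as haplotype_table: every site called
            # cleanly as ref or edited
            if set(calls) != set(labels) or any(
                v not in ("ref", "edited") for v in calls.values()
            ):
                continue
        for lab, call in calls.items():
            if call == "ref":
                tallies[lab][0] += 1
            elif call == "edited":
                tallies[lab][1] += 1
            elif call == "other":
                tallies[lab][2] += 1
    return [
        SiteEditingResult(sample_id, lab, *tallies[lab]) for lab in labels
    ]


def haplotype_table(
    alignments,
    sites: Sequence[EditingSiteSpec],
    min_baseq: int = DEFAULT_MIN_BASEQ,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    sample_id: str = "sample",
) -> EditingHaplotypeTable:
    """Per-read editing-combination counts over reads covering every site.

    The combination string lists the edited site labels in spec order; the
    empty string is the unedited haplotype.  Reads with an 'other' base or a
    quality-failed call at any site are excluded.
    """
    af = _open(alignments)
    labels = [s.site_label for s in sites]
    counts: dict[str, int] = {}
    for read in af:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality < min_mapq:
            continue
        calls = _read_site_calls(read, sites, min_baseq)
        if set(calls) != set(labels):
            continue
        if any(v is None or v == "other" for v in calls.values()):
            continue
        combo = "".join(lab for lab in labels if calls[lab] == "edited")
        counts[combo] = counts.get(combo, 0) + 1
    if not counts:
        raise ValueError(
            "no read covers all editing sites; use long-read or amplicon input"
        )
    return EditingHaplotypeTable(sample_id, counts)


def exon_skipping(
    alignments,
    inclusion_junctions: Sequence[tuple[int, int]],
    skipping_junction: tuple[int, int],
    chrom: str | None = None,
    min_overhang: int = 8,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    sample_id: str = "sample",
) -> SkippingResult:
    """Alternative 5' splice-site usage from exact junction-gap matching.

    A read votes for inclusion when one of its N-gaps exactly matches an
    inclusion junction (proximal splice site, alternative exon included)
    and for skipping when a gap matches the skipping junction (distal
    splice site).
    """
    af = _open(alignments)
    incl = set(map(tuple, inclusion_junctions))
    skip = tuple(skipping_junction)
    n_incl = n_skip = 0
    for read in af:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality < min_mapq:
            continue
        if chrom is not None and read.reference_name != chrom:
            continue
        pos = read.reference_start
        gaps = []
        for op, length in read.cigartuples:
            if op in (0, 2, 7, 8):
                pos += length
            elif op == 3:
                gaps.append((pos, pos + length))
                pos += length
        gapset = set(gaps)
        if gapset & incl:
            n_incl += 1
        elif skip in gapset:
            n_skip += 1
    return SkippingResult(sample_id, n_incl, n_skip)


@dataclass
class SiteComparison:
    site_label: str
    fraction_a: float
    fraction_b: float
    p_value: float
    p_adj: float
    significant: bool


def compare_site_editing(
    results_a: Sequence[SiteEditingResult],
    results_b: Sequence[SiteEditingResult],
    alpha: float = 0.05,
) -> list[SiteComparison]:
    """Per-site two-proportion z-test between conditions, BH-corrected."""
    by_label_b = {r.site_label: r for r in results_b}
    rows = []
    for ra in results_a:
        rb = by_label_b[ra.site_label]
        na, nb = ra.n_ref + ra.n_edited, rb.n_ref + rb.n_edited
        if na == 0 or nb == 0:
            rows.append((ra.site_label, float("nan"), float("nan"), 1.0))
            continue
        if ra.n_edited + rb.n_edited in (0, na + nb):
            p = 1.0  # identical degenerate proportions
        else:
            _, p = proportions_ztest([ra.n_edited, rb.n_edited], [na, nb])
        rows.append((ra.site_label, ra.editing_fraction, rb.editing_fraction, float(p)))
    padj = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    return [
        SiteComparison(lab, fa, fb, p, float(q), bool(q <= alpha))
        for (lab, fa, fb, p), q in zip(rows, padj)
    ]
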