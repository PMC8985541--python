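"""Single-molecule validation of retained-intron candidates.

A long read validates retention when it covers both exon/intron boundaries
contiguously (no splice gap) and most of the intron body; it supports
splicing when an alignment gap matches both annotated boundaries within a
small slack.  Because whole molecules are sequenced, exon/intron
connectivity is read directly off the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pysam

from .genome_model import IntronRecord

DEFAULT_SLACK = 10
DEFAULT_FLANK = 10
DEFAULT_BODY_COV_MIN = 0.8
DEFAULT_MIN_SUPPORT = 1

_SUPPORTED_OPS = {0, 1, 2, 3, 4, 5, 7, 8}


@dataclass
class LongReadCall:
    read_id: str
    intron_id: str
    verdict: str  # "retained" | "spliced" | "uninformative"
    intron_body_coverage: float
    gap_match_slack: int | None  # max boundary distance of the matching gap


@dataclass
class ValidationSummary:
    intron_id: str
    n_retained_reads: int
    n_spliced_reads: int
    validated: bool
    condition_id: str = ""


def _blocks_and_gaps(read: pysam.AlignedSegment):
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    pos = read.reference_start
    cur = pos
    has = False
    for op, length in read.cigartuples:
        if op not in _SUPPORTED_OPS:
            return None
        if op in (0, 2, 7, 8):
            pos += length
            has = True
        elif op == 3:
            if has:
                blocks.append((cur, pos))
            gaps.append((pos, pos + length))
            pos += length
            cur = pos
            has = False
    if has:
        blocks.append((cur, pos))
    return blocks, gaps


def _covered_within(blocks: Sequence[tuple[int, int]], start: int, end: int) -> int:
    return sum(max(0, min(be, end) - max(bs, start)) for bs, be in blocks)


def classify_long_read(
    read: pysam.AlignedSegment,
    intron: IntronRecord,
    slack: int = DEFAULT_SLACK,
    flank: int = DEFAULT_FLANK,
    body_cov_min: float = DEFAULT_BODY_COV_MIN,
    qc: dict | None = None,
) -> LongReadCall:
    """Classify one spliced long-read alignment against one intron.

    Total function: malformed CIGARs yield an uninformative call and a QC
    tally.  Small indels are tolerated because deletions keep a block
    contiguous and boundary matching allows ``slack`` nt.
    """
    uninformative = LongReadCall(
        read.query_name or "", intron.intron_id, "uninformative", 0.0, None
    )
    if read.is_unmapped or read.cigartuples is None:
        if qc is not None:
            qc["uninformative_unmapped"] = qc.get("uninformative_unmapped", 0) + 1
        return uninformative
    bg = _blocks_and_gaps(read)
    if bg is None:
        if qc is not None:
            qc["uninformative_bad_cigar"] = qc.get("uninformative_bad_cigar", 0) + 1
        return uninformative
    blocks, gaps = bg

    body_len = intron.end - intron.start
    body_cov = _covered_within(blocks, intron.start, intron.end) / body_len

    # spliced: an N-gap matching both boundaries within slack
    best = None
    for gs, ge in gaps:
        d = max(abs(gs - intron.start), abs(ge - intron.end))
        if d <= slack and (best is None or d < best):
            best = d
    if best is not None:
        return LongReadCall(
            read.query_name or "", intron.intron_id, "spliced", body_cov, best
        )

    # retained: both boundary windows inside a single aligned block, plus
    # sufficient intron-body coverage
    windows = (
        (intron.start - flank, intron.start + flank),
        (intron.end - flank, intron.end + flank),
    )
    boundaries_ok = all(
        any(bs <= ws and we <= be for bs, be in blocks) for ws, we in windows
    )
    if boundaries_ok and body_cov >= body_cov_min:
        return LongReadCall(
            read.query_name or "", intron.intron_id, "retained", body_cov, None
        )
    return LongReadCall(
        read.query_name or "", intron.intron_id, "uninformative", body_cov, None
    )


def classify_alignments(
    alignments,
    introns: Sequence[IntronRecord],
    slack: int = DEFAULT_SLACK,
    flank: int = DEFAULT_FLANK,
    body_cov_min: float = DEFAULT_BODY_COV_MIN,
    qc: dict | None = None,
) -> list[LongReadCall]:
    """Classify every primary alignment against every overlapping intron."""
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
    by_chrom: dict[str, list[IntronRecord]] = {}
    for i in introns:
        by_chrom.setdefault(i.chrom, []).append(i)
    calls = []
    for read in alignments:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        for intron in by_chrom.get(read.reference_name, []):
            if read.reference_start >= intron.end + DEFAULT_FLANK:
                continue
            if read.reference_end <= intron.start - DEFAULT_FLANK:
                continue
            calls.append(
                classify_long_read(read, intron, slack, flank, body_cov_min, qc)
            )
    return calls


def validate_candidates(
    calls: Iterable[LongReadCall],
    candidates: Sequence,
    min_support: int = DEFAULT_MIN_SUPPORT,
    condition_id: str = "",
) -> tuple[list[ValidationSummary], float, list[str]]:
    """Summarize long-read support per candidate retained intron.

    ``candidates`` may be intron ids or objects with an ``intron_id``
    attribute (e.g. RiCall).  Returns per-intron summaries, the validation
    rate over candidates with at least one informative read, and the list of
    candidates with no informative read.
    """
    cand_ids = [getattr(c, "intron_id", c) for c in candidates]
    if not cand_ids:
        raise ValueError("empty candidate list")
    tallies: dict[str, list[int]] = {c: [0, 0] for c in cand_ids}
    for call in calls:
        if call.intron_id not in tallies:
            continue
        if call.verdict == "retained":
            tallies[call.intron_id][0] += 1
        elif call.verdict == "spliced":
            tallies[call.intron_id][1] += 1
    summaries = []
    no_info = []
    n_validated = 0
    n_informative = 0
    for cid in cand_ids:
        n_ret, n_spl = tallies[cid]
        if n_ret + n_spl == 0:
            no_info.append(cid)
            continue
        n_informative += 1
        validated = n_ret >= min_support
        n_validated += validated
        summaries.append(ValidationSummary(cid, n_ret, n_spl, validated, condition_id))
    rate = n_validated / n_informative if n_informative else float("nan")
    return summaries, rate, no_info
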