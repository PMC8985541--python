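"""Gene models, introns and genome sequence access.

All coordinates inside the package are 0-based half-open on the forward
genomic strand; strand only matters when extracting sequence or assigning
donor/acceptor roles.  GTF input/output uses the conventional 1-based
inclusive coordinates and is converted at the boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from pyfaidx import Fasta

DEFAULT_MIN_INTRON_LENGTH = 30


class GtfParseError(ValueError):
    """Raised when a GTF file cannot be parsed into gene models."""


@dataclass
class GeneModel:
    """A gene with its exon catalogue and transcript structures.

    ``exons`` is the deduplicated, genomically sorted list of exon intervals
    used by this gene; each transcript is a list of indices into it.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    transcripts: list[list[int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(
                    f"{self.gene_id}: exon ({s},{e}) outside span "
                    f"({self.tx_start},{self.tx_end})"
                )
        for t in self.transcripts:
            if not t:
                raise ValueError(f"{self.gene_id}: transcript with zero exons")
            ivs = sorted(self.exons[i] for i in t)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"{self.gene_id}: overlapping exons within a transcript"
                    )

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged union of all exon intervals of the gene."""
        merged: list[list[int]] = []
        for s, e in sorted(self.exons):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exon_union())

    def longest_transcript_span(self) -> tuple[int, int]:
        """Span (start, end) of the transcript covering the widest interval."""
        best: tuple[int, int] | None = None
        for t in self.transcripts:
            ivs = [self.exons[i] for i in t]
            span = (min(s for s, _ in ivs), max(e for _, e in ivs))
            if best is None or span[1] - span[0] > best[1] - best[0]:
                best = span
        assert best is not None
        return best


@dataclass(frozen=True)
class IntronRecord:
    """A single intron, strand-aware: the donor is the 5' splice site."""

    intron_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    ordinal: int
    known_retained: bool = False

    @property
    def donor_pos(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor_pos(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class GenomeSequence:
    """Nucleotide sequence per chromosome with strand-aware lookup."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = sequences

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeSequence":
        fa = Fasta(str(path), as_raw=True, read_ahead=10_000_000)
        seqs = {name: str(fa[name][:]).upper() for name in fa.keys()}
        fa.close()
        return cls(seqs)

    def to_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sequences):
                fh.write(f">{name}\n")
                s = self.sequences[name]
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end); reverse-complemented for strand '-'."""
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq):
            raise IndexError(f"window ({start},{end}) off chromosome {chrom}")
        sub = seq[start:end]
        return reverse_complement(sub) if strand == "-" else sub


def _validate_gtf_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end < start:
                raise GtfParseError(
                    f"{path}: line {lineno}: end ({end}) < start ({start})"
                )


def load_gene_models(gtf_path: str | os.PathLike) -> list[GeneModel]:
    """Read a GTF (Ensembl dialect) and build one :class:`GeneModel` per gene.

    Exon features must carry ``gene_id`` and ``transcript_id`` attributes.
    Coordinates are converted from GTF 1-based inclusive to internal 0-based
    half-open.  Output is deterministically ordered by (chrom, tx_start,
    gene_id).
    """
    path = Path(gtf_path)
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    # gene_id -> {transcript_id -> [(start, end)]}, plus per-gene metadata
    per_gene: dict[str, dict[str, list[tuple[int, int]]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in db.features_of_type("exon"):
        try:
            gid = feat.attributes["gene_id"][0]
            tid = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise GtfParseError(
                f"{path}: exon at {feat.seqid}:{feat.start} missing "
                f"gene_id/transcript_id attribute"
            ) from exc
        iv = (feat.start - 1, feat.end)
        per_gene.setdefault(gid, {}).setdefault(tid, []).append(iv)
        prev = meta.setdefault(gid, (feat.seqid, feat.strand))
        if prev != (feat.seqid, feat.strand):
            raise GtfParseError(
                f"{path}: gene {gid} spans multiple chromosomes or strands"
            )

    genes: list[GeneModel] = []
    for gid, txs in per_gene.items():
        chrom, strand = meta[gid]
        exon_set = sorted({iv for ivs in txs.values() for iv in ivs})
        index = {iv: i for i, iv in enumerate(exon_set)}
        transcripts = []
        for tid in sorted(txs):
            ivs = sorted(txs[tid])
            if not ivs:
                raise GtfParseError(f"{path}: transcript of gene {gid} has no exons")
            transcripts.append([index[iv] for iv in ivs])
        tx_start = min(s for s, _ in exon_set)
        tx_end = max(e for _, e in exon_set)
        genes.append(
            GeneModel(gid, chrom, strand, tx_start, tx_end, exon_set, transcripts)
        )
    genes.sort(key=lambda g: (g.chrom, g.tx_start, g.gene_id))
    return genes


def write_gene_models(
    genes: Iterable[GeneModel], gtf_path: str | os.PathLike, source: str = "riquant"
) -> None:
    """Write gene models back to GTF (1-based inclusive coordinates)."""
    with open(gtf_path, "w") as fh:
        for g in genes:
            for ti, t in enumerate(g.transcripts, 1):
                tid = f"{g.gene_id}.t{ti}"
                for s, e in sorted(g.exons[i] for i in t):
                    attrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                    fh.write(
                        "\t".join(
                            [
                                g.chrom,
                                source,
                                "exon",
                                str(s + 1),
                                str(e),
                                ".",
                                g.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def derive_introns(
    gene: GeneModel,
    min_intron_length: int = DEFAULT_MIN_INTRON_LENGTH,
    report: dict | None = None,
) -> list[IntronRecord]:
    """Introns of a gene: gaps between consecutive exons of each transcript.

    Introns are deduplicated by (start, end) across transcripts.  Ordinals
    follow transcription order (genomic order reversed for minus-strand
    genes).  An intron wholly contained in another transcript's exon is
    flagged ``known_retained`` — the annotation itself documents a retained
    form.  Gaps shorter than ``min_intron_length`` are excluded and counted
    in ``report["short_gaps_skipped"]`` when a report dict is supplied.
    """
    gaps: set[tuple[int, int]] = set()
    n_short = 0
    for t in gene.transcripts:
        ivs = sorted(gene.exons[i] for i in t)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 - e1 <= 0:
                continue
            if s2 - e1 < min_intron_length:
                n_short += 1
                continue
            gaps.add((e1, s2))
    if report is not None:
        report["short_gaps_skipped"] = report.get("short_gaps_skipped", 0) + n_short

    ordered = sorted(gaps)
    if gene.strand == "-":
        ordered = ordered[::-1]
    records = []
    for k, (s, e) in enumerate(ordered, 1):
        retained = any(
            es <= s and e <= ee
            for t in gene.transcripts
            for es, ee in (gene.exons[i] for i in t)
        )
        records.append(
            IntronRecord(
                intron_id=f"{gene.gene_id}:{s}-{e}",
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                start=s,
                end=e,
                ordinal=k,
                known_retained=retained,
            )
        )
    return records


def derive_all_introns(
    genes: Sequence[GeneModel],
    min_intron_length: int = DEFAULT_MIN_INTRON_LENGTH,
    report: dict | None = None,
) -> list[IntronRecord]:
    out: list[IntronRecord] = []
    for g in genes:
        out.extend(derive_introns(g, min_intron_length, report))
    return out
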