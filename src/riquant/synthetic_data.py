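"""Fully specified synthetic inputs with ground truth.

Generates a random genome with non-overlapping multi-exon genes (consensus
GT..AG splice sites with consensus-biased donor/acceptor windows so
splice-model training has signal), strand-specific spliced short reads with
per-intron retention fractions that differ by condition, polyadenylated
full-length long reads with per-molecule retention, and amplicon-style
edited reads over a five-site A-to-I cluster next to an alternatively
spliced exon.  Everything is emitted as already-aligned SAM built from the
known molecule structure — the aligner is not part of the computation under
test — together with truth tables.

The default configuration mirrors the emulated study design: four
conditions (AI, AN, BI, BN) with three replicates each, 150 nt
strand-specific reads with 98% strandedness, and polyadenylated long
reads.  Identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .editing_analysis import EditingSiteSpec
from .genome_model import (
    GeneModel,
    GenomeSequence,
    IntronRecord,
    derive_all_introns,
    write_gene_models,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic data generator."""

    seed: int
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_length: tuple[int, int] = (100, 250)
    intron_length: tuple[int, int] = (60, 300)
    conditions: tuple[str, ...] = ("AI", "AN", "BI", "BN")
    replicates: int = 3
    read_length: int = 150
    reads_per_gene: int = 300
    longread_depth: int = 20
    strandedness: float = 0.98
    error_rate: float = 0.001
    rho_retained: float = 0.5
    rho_background: float = 0.02
    frac_retained_introns: float = 0.2
    frac_condition_specific: float = 0.5
    minus_strand_fraction: float = 0.5
    intergenic_spacer: int = 3500
    consensus_match_prob: float = 0.85
    lr_truncation_prob: float = 0.2
    lr_indel_rate: float = 0.002
    editing_enabled: bool = True
    editing_haplotypes: dict[str, float] = field(
        default_factory=lambda: {"ABD": 0.35, "AB": 0.25, "ABCD": 0.20, "": 0.20}
    )
    skipping_fraction: float = 0.25
    editing_reads: int = 1000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.rho_retained <= 1.0 or not 0.0 <= self.rho_background <= 1.0:
            raise ValueError("retention fractions must be in [0, 1]")
        total = sum(self.editing_haplotypes.values())
        if self.editing_enabled and abs(total - 1.0) > 1e-9:
            raise ValueError("editing haplotype probabilities must sum to 1")

    def sample_ids(self) -> list[str]:
        return [
            f"{cond}_rep{r}" for cond in self.conditions for r in range(1, self.replicates + 1)
        ]


@dataclass
class EditingLocus:
    chrom: str
    gene_id: str
    sites: list[EditingSiteSpec]
    inclusion_junctions: list[tuple[int, int]]
    skipping_junction: tuple[int, int]
    region: tuple[int, int]


@dataclass
class TruthTable:
    """Ground truth the generator wrote into the data."""

    rho: pd.DataFrame  # introns x conditions, true retention fraction
    editing_marginals: dict[str, float] = field(default_factory=dict)
    editing_haplotypes: dict[str, float] = field(default_factory=dict)
    skipping_fraction: float = float("nan")
    pir_threshold: float = 25.0

    def expected_retained(self) -> pd.DataFrame:
        return 100.0 * self.rho > self.pir_threshold

    def expected_switches(self, cond_a: str, cond_b: str) -> pd.Series:
        exp = self.expected_retained()
        return exp[cond_a] != exp[cond_b]


@dataclass
class GeneLayout:
    """Transcription-order segment layout of one synthetic gene."""

    gene: GeneModel
    # (kind, length, genomic_start, genomic_end, intron_index or -1),
    # ordered 5'->3' along the transcript
    segments: list[tuple[str, int, int, int, int]]
    intron_ids: list[str]  # transcription order


@dataclass
class LocusSet:
    genome: GenomeSequence
    genes: list[GeneModel]
    introns: list[IntronRecord]
    layouts: dict[str, GeneLayout]
    truth: TruthTable
    editing: EditingLocus | None = None
    chrom: str = "chrS"

    def intron_by_id(self) -> dict[str, IntronRecord]:
        return {i.intron_id: i for i in self.introns}

    def write(self, outdir: str | os.PathLike) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "truth": outdir / "truth_rho.tsv",
        }
        self.genome.to_fasta(paths["fasta"])
        write_gene_models(self.genes, paths["gtf"])
        self.truth.rho.round(6).to_csv(paths["truth"], sep="\t")
        if self.editing is not None:
            paths["editing_sites"] = outdir / "editing_sites.tsv"
            with open(paths["editing_sites"], "w") as fh:
                for s in self.editing.sites:
                    fh.write(f"{s.chrom}\t{s.position}\t{s.strand}\t{s.site_label}\n")
        return paths


def _biased_window(rng: np.random.Generator, consensus: str, p: float, fixed: set[int]) -> str:
    out = []
    for i, b in enumerate(consensus):
        if i in fixed or rng.random() < p:
            out.append(b)
        else:
            out.append(str(rng.choice([x for x in "ACGT" if x != b])))
    return "".join(out)


# donor: 3 exonic (CAG) | 6 intronic (GTAAGT, GT fixed)
_DONOR_CONSENSUS = "CAGGTAAGT"
_DONOR_FIXED = {3, 4}
# acceptor: 20 intronic (18 nt polypyrimidine + AG fixed) | 3 exonic (GTC)
_ACCEPTOR_CONSENSUS = "T" * 12 + "TTTTCC" + "AG" + "GTC"
_ACCEPTOR_FIXED = {18, 19}


def _default_retention_plan(
    intron_ids: Sequence[str], cfg: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """rho per intron per condition: mostly background, a retained subset.

    Of the retained subset, ``frac_condition_specific`` are retained in a
    single (round-robin) condition; the rest in every condition.
    """
    rho = pd.DataFrame(
        cfg.rho_background, index=list(intron_ids), columns=list(cfg.conditions)
    )
    n_ret = int(round(cfg.frac_retained_introns * len(intron_ids)))
    chosen = rng.choice(len(intron_ids), size=n_ret, replace=False)
    chosen.sort()
    n_specific = int(round(cfg.frac_condition_specific * n_ret))
    for k, idx in enumerate(chosen):
        iid = intron_ids[idx]
        if k < n_specific:
            cond = cfg.conditions[k % len(cfg.conditions)]
            rho.loc[iid, cond] = cfg.rho_retained
        else:
            rho.loc[iid, :] = cfg.rho_retained
    return rho


def make_locus_set(cfg: SyntheticConfig) -> LocusSet:
    """Random genome + gene models + truth table under one seed."""
    rng = np.random.default_rng([cfg.seed, 0])
    chrom = "chrS"
    genes: list[GeneModel] = []
    layouts: dict[str, GeneLayout] = {}
    pieces: list[str] = []
    cursor = 0

    def spacer() -> None:
        nonlocal cursor
        n = cfg.intergenic_spacer
        pieces.append("".join(rng.choice(_BASES, size=n)))
        cursor += n

    spacer()
    for gi in range(cfg.n_genes):
        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exon_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_exons)
        intron_lens = rng.integers(
            cfg.intron_length[0], cfg.intron_length[1] + 1, size=n_exons - 1
        )
        # sense-strand pre-mRNA
        sense = []
        seg_plan: list[tuple[str, int]] = []  # transcription order
        for k in range(n_exons):
            sense.append("".join(rng.choice(_BASES, size=int(exon_lens[k]))))
            seg_plan.append(("exon", int(exon_lens[k])))
            if k < n_exons - 1:
                sense.append("".join(rng.choice(_BASES, size=int(intron_lens[k]))))
                seg_plan.append(("intron", int(intron_lens[k])))
        seq = list("".join(sense))
        # consensus-biased splice sites at every exon|intron boundary (sense)
        off = 0
        for kind, length in seg_plan:
            if kind == "intron":
                donor = _biased_window(rng, _DONOR_CONSENSUS, cfg.consensus_match_prob, _DONOR_FIXED)
                seq[off - 3 : off + 6] = donor
                acc = _biased_window(
                    rng, _ACCEPTOR_CONSENSUS, cfg.consensus_match_prob, _ACCEPTOR_FIXED
                )
                seq[off + length - 20 : off + length + 3] = acc
            off += length
        sense_seq = "".join(seq)
        L = len(sense_seq)
        gstart = cursor
        from .genome_model import reverse_complement

        pieces.append(sense_seq if strand == "+" else reverse_complement(sense_seq))
        cursor += L

        # genomic coordinates of segments, transcription order
        gene_id = f"G{gi:03d}"
        segments: list[tuple[str, int, int, int, int]] = []
        off = 0
        intron_idx = 0
        for kind, length in seg_plan:
            if strand == "+":
                a, b = gstart + off, gstart + off + length
            else:
                a, b = gstart + L - off - length, gstart + L - off
            segments.append((kind, length, a, b, intron_idx if kind == "intron" else -1))
            if kind == "intron":
                intron_idx += 1
            off += length
        exon_ivs = sorted((a, b) for kind, _, a, b, _ in segments if kind == "exon")
        gene = GeneModel(
            gene_id, chrom, strand, gstart, gstart + L, exon_ivs,
            [list(range(len(exon_ivs)))],
        )
        genes.append(gene)
        intron_segs = [(a, b) for kind, _, a, b, _ in segments if kind == "intron"]
        intron_ids = [f"{gene_id}:{a}-{b}" for a, b in intron_segs]
        layouts[gene_id] = GeneLayout(gene, segments, intron_ids)
        spacer()

    editing = None
    if cfg.editing_enabled:
        editing, edit_piece = _make_editing_locus(cfg, rng, chrom, cursor)
        pieces.append(edit_piece)
        cursor += len(edit_piece)
        pieces.append("".join(rng.choice(_BASES, size=cfg.intergenic_spacer)))
        cursor += cfg.intergenic_spacer

    genome = GenomeSequence({chrom: "".join(pieces)})
    introns = derive_all_introns(genes)
    plan_rng = np.random.default_rng([cfg.seed, 1])
    all_ids = [iid for g in genes for iid in layouts[g.gene_id].intron_ids]
    rho = _default_retention_plan(all_ids, cfg, plan_rng)
    marginals = {}
    if cfg.editing_enabled:
        for lab in "ABCDE":
            marginals[lab] = sum(
                p for h, p in cfg.editing_haplotypes.items() if lab in h
            )
    truth = TruthTable(
        rho=rho,
        editing_marginals=marginals,
        editing_haplotypes=dict(cfg.editing_haplotypes),
        skipping_fraction=cfg.skipping_fraction if cfg.editing_enabled else float("nan"),
    )
    return LocusSet(genome, genes, introns, layouts, truth, editing, chrom)


def _make_editing_locus(
    cfg: SyntheticConfig, rng: np.random.Generator, chrom: str, cursor: int
) -> tuple[EditingLocus, str]:
    """A plus-strand three-exon locus: flanking exons, an alternative exon
    carrying five A editing sites, and proximal/distal 5' splice sites."""
    e1, i1, vb, i2, e3 = 200, 150, 120, 150, 200
    seq = list("".join(rng.choice(_BASES, size=e1 + i1 + vb + i2 + e3)))
    vb_start = cursor + e1 + i1
    site_offsets = [20, 40, 60, 75, 95]
    for off in site_offsets:
        seq[e1 + i1 + off] = "A"
    sites = [
        EditingSiteSpec(lab, chrom, vb_start + off, "+")
        for lab, off in zip("ABCDE", site_offsets)
    ]
    e1_end = cursor + e1
    e3_start = cursor + e1 + i1 + vb + i2
    editing = EditingLocus(
        chrom=chrom,
        gene_id="EDIT",
        sites=sites,
        inclusion_junctions=[(e1_end, vb_start), (vb_start + vb, e3_start)],
        skipping_junction=(e1_end, e3_start),
        region=(cursor, e3_start + e3),
    )
    return editing, "".join(seq)


def _sam_header(genome: GenomeSequence) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": c, "LN": l} for c, l in sorted(genome.lengths().items())
            ],
        }
    )


def _write_sam(path: Path, genome: GenomeSequence, records: list[dict]) -> None:
    header = _sam_header(genome)
    records.sort(key=lambda r: (r["chrom"], r["pos"], r["qname"]))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(header)
            a.query_name = r["qname"]
            a.query_sequence = r["seq"]
            a.flag = 16 if r["reverse"] else 0
            a.reference_id = out.get_tid(r["chrom"])
            a.reference_start = r["pos"]
            a.mapping_quality = 60
            a.cigartuples = r["cigar"]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r["seq"]))
            out.write(a)


def _merge_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    blocks = sorted(blocks)
    merged: list[list[int]] = []
    for s, e in blocks:
        if merged and s == merged[-1][1]:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    cigar = []
    for k, (s, e) in enumerate(blocks):
        if k:
            cigar.append((3, s - blocks[k - 1][1]))  # N
        cigar.append((0, e - s))  # M
    return cigar


def _molecule_blocks_genomic(
    layout: GeneLayout, retained: np.ndarray
) -> list[tuple[int, int]]:
    """Genomic blocks of a whole molecule (exons + retained introns), merged."""
    blocks = [
        (a, b)
        for kind, _, a, b, ii in layout.segments
        if kind == "exon" or retained[ii]
    ]
    return _merge_blocks(blocks)


def _transcript_to_genomic(
    layout: GeneLayout, retained: np.ndarray, t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval of a molecule to genomic blocks.

    Transcript coordinates run 5'->3' over the kept segments (exons plus
    retained introns) in transcription order.
    """
    strand = layout.gene.strand
    blocks: list[tuple[int, int]] = []
    cum = 0
    for kind, length, a, b, ii in layout.segments:
        if kind == "intron" and not retained[ii]:
            continue
        lo, hi = cum, cum + length
        cum = hi
        s = max(t_start, lo)
        e = min(t_end, hi)
        if s >= e:
            continue
        if strand == "+":
            blocks.append((a + (s - lo), a + (e - lo)))
        else:
            blocks.append((b - (e - lo), b - (s - lo)))
    return _merge_blocks(blocks)


def _read_seq(genome: GenomeSequence, chrom: str, blocks, rng, error_rate: float) -> str:
    seq = "".join(genome.sequences[chrom][s:e] for s, e in blocks)
    if error_rate > 0:
        arr = np.array(list(seq))
        errs = np.nonzero(rng.random(len(arr)) < error_rate)[0]
        for i in errs:
            arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
        seq = "".join(arr)
    return seq


def _draw_retention(
    rng: np.random.Generator, rho: np.ndarray, lengths: dict, read_length: int
) -> tuple[np.ndarray, int]:
    """Retention vector weighted by the molecule's fragment capacity.

    Fragment sampling draws a read uniformly from the pooled start
    positions of all molecules, so the molecule type of a read must be
    weighted by its number of start positions (L - read_length + 1), not by
    abundance alone; rejection sampling with that acceptance keeps the
    junction-read fraction at a boundary equal to rho exactly.
    """
    exonic, intron_lens, l_max = lengths["exonic"], lengths["introns"], lengths["max"]
    w_max = max(l_max - read_length + 1, 1)
    while True:
        v = rng.random(len(rho)) < rho
        L = exonic + int(intron_lens[v].sum()) if len(rho) else exonic
        w = max(L - read_length + 1, 0)
        if rng.random() < w / w_max:
            return v, L


def simulate_short_reads(
    cfg: SyntheticConfig,
    locus: LocusSet,
    outdir: str | os.PathLike,
    single_end: bool = True,
) -> dict[str, Path]:
    """Strand-specific spliced short reads per sample, as aligned SAM.

    Per read, a molecule is drawn with per-intron Bernoulli retention at the
    condition's true rho (length-weighted, see :func:`_draw_retention`), the
    read start is uniform along the molecule, and the CIGAR carries N-gaps
    exactly at spliced introns.  The read strand matches the gene strand
    with probability ``strandedness``.
    """
    if not single_end:
        raise NotImplementedError("paired-end emission not implemented; single-end default")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    rho = locus.truth.rho
    skipped = 0
    for si, sample in enumerate(cfg.sample_ids()):
        cond = sample.rsplit("_rep", 1)[0]
        rng = np.random.default_rng([cfg.seed, 2, si])
        records: list[dict] = []
        for gene in locus.genes:
            layout = locus.layouts[gene.gene_id]
            n_introns = len(layout.intron_ids)
            intron_lens = np.array(
                [l for kind, l, *_ in layout.segments if kind == "intron"], dtype=int
            )
            exonic = sum(l for kind, l, *_ in layout.segments if kind == "exon")
            lengths = {
                "exonic": exonic,
                "introns": intron_lens,
                "max": exonic + int(intron_lens.sum()),
            }
            rho_vec = (
                rho.loc[layout.intron_ids, cond].to_numpy(dtype=float)
                if n_introns
                else np.empty(0)
            )
            for ri in range(cfg.reads_per_gene):
                v, L = _draw_retention(rng, rho_vec, lengths, cfg.read_length)
                if L < cfg.read_length:
                    skipped += 1
                    continue
                mol_blocks = _molecule_blocks_genomic(layout, v)
                # uniform start in genomic-order molecule coordinates
                m = int(rng.integers(0, L - cfg.read_length + 1))
                blocks = []
                cum = 0
                for s, e in mol_blocks:
                    lo, hi = cum, cum + (e - s)
                    cum = hi
                    a = max(m, lo)
                    b = min(m + cfg.read_length, hi)
                    if a < b:
                        blocks.append((s + a - lo, s + b - lo))
                sense = rng.random() < cfg.strandedness
                reverse = (gene.strand == "-") == sense
                records.append(
                    {
                        "qname": f"{gene.gene_id}.{sample}.{ri}",
                        "chrom": locus.chrom,
                        "pos": blocks[0][0],
                        "cigar": _blocks_to_cigar(blocks),
                        "seq": _read_seq(locus.genome, locus.chrom, blocks, rng, cfg.error_rate),
                        "reverse": reverse,
                    }
                )
        path = outdir / f"{sample}.sam"
        _write_sam(path, locus.genome, records)
        paths[sample] = path
    return paths


def simulate_long_reads(
    cfg: SyntheticConfig,
    locus: LocusSet,
    outdir: str | os.PathLike,
) -> dict[str, Path]:
    """Polyadenylated full-length long reads per condition, as aligned SAM.

    Per-molecule retention follows the condition's rho; a configurable
    fraction of molecules is 5'-truncated (long direct-RNA reads anchor at
    the 3' end), and small deletions emulate indel noise.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    rho = locus.truth.rho
    for ci, cond in enumerate(cfg.conditions):
        rng = np.random.default_rng([cfg.seed, 3, ci])
        records: list[dict] = []
        for gene in locus.genes:
            layout = locus.layouts[gene.gene_id]
            n_introns = len(layout.intron_ids)
            rho_vec = (
                rho.loc[layout.intron_ids, cond].to_numpy(dtype=float)
                if n_introns
                else np.empty(0)
            )
            for mi in range(cfg.longread_depth):
                v = rng.random(n_introns) < rho_vec
                L = sum(
                    l
                    for kind, l, *_rest in layout.segments
                    if kind == "exon" or v[_rest[-1]]
                )
                t0 = 0
                if cfg.lr_truncation_prob > 0 and rng.random() < cfg.lr_truncation_prob:
                    t0 = int(rng.integers(1, max(L - 200, 2)))
                blocks = _transcript_to_genomic(layout, v, t0, L)
                blocks = _apply_deletions(blocks, rng, cfg.lr_indel_rate)
                records.append(
                    {
                        "qname": f"{gene.gene_id}.{cond}.lr{mi}",
                        "chrom": locus.chrom,
                        "pos": blocks[0][0][0] if isinstance(blocks[0], list) else blocks[0][0],
                        "cigar": _segments_to_cigar(blocks),
                        "seq": _lr_seq(locus.genome, locus.chrom, blocks),
                        "reverse": gene.strand == "-",
                    }
                )
        path = outdir / f"longreads_{cond}.sam"
        _write_sam(path, locus.genome, records)
        paths[cond] = path
    return paths


def _apply_deletions(blocks, rng: np.random.Generator, rate: float):
    """Split aligned blocks by small deletions at the given per-nt rate.

    Returns a list of groups; each group is a list of sub-blocks separated
    by deletions, groups are separated by splice gaps.
    """
    groups = []
    for s, e in blocks:
        n_del = rng.poisson(rate * (e - s)) if rate > 0 else 0
        cuts = []
        for _ in range(n_del):
            dlen = int(rng.integers(1, 4))
            pos = int(rng.integers(s + 1, max(e - dlen - 1, s + 2)))
            cuts.append((pos, pos + dlen))
        cuts = [c for c in sorted(cuts) if c[1] < e]
        sub = []
        prev = s
        for cs, ce in cuts:
            if cs <= prev:
                continue
            sub.append((prev, cs))
            prev = ce
        sub.append((prev, e))
        groups.append(sub)
    return groups


def _segments_to_cigar(groups) -> list[tuple[int, int]]:
    cigar: list[tuple[int, int]] = []
    prev_end = None
    for sub in groups:
        if prev_end is not None:
            cigar.append((3, sub[0][0] - prev_end))  # N splice gap
        for k, (s, e) in enumerate(sub):
            if k:
                cigar.append((2, s - sub[k - 1][1]))  # D
            cigar.append((0, e - s))
        prev_end = sub[-1][1]
    return cigar


def _lr_seq(genome: GenomeSequence, chrom: str, groups) -> str:
    return "".join(
        genome.sequences[chrom][s:e] for sub in groups for s, e in sub
    )


def simulate_editing_reads(
    cfg: SyntheticConfig,
    locus: LocusSet,
    out_path: str | os.PathLike,
    n_reads: int | None = None,
    haplotypes: Mapping[str, float] | None = None,
    skipping_fraction: float | None = None,
    stream: int = 0,
) -> Path:
    """Amplicon-style reads over the editing locus, as aligned SAM.

    Every read spans the whole locus; with probability ``skipping_fraction``
    the alternative exon is skipped (distal splice site), otherwise the
    read covers all five sites and its haplotype is drawn from the
    configured distribution.
    """
    if locus.editing is None:
        raise ValueError("locus has no editing locus (editing_enabled=False)")
    ed = locus.editing
    n_reads = n_reads if n_reads is not None else cfg.editing_reads
    haplotypes = dict(haplotypes if haplotypes is not None else cfg.editing_haplotypes)
    skip_frac = (
        skipping_fraction if skipping_fraction is not None else cfg.skipping_fraction
    )
    rng = np.random.default_rng([cfg.seed, 4, stream])
    labels = list(haplotypes)
    probs = np.array([haplotypes[h] for h in labels], dtype=float)
    probs = probs / probs.sum()

    (e1s, e1e), (vbs, vbe), (e3s, e3e) = (
        (ed.region[0], ed.inclusion_junctions[0][0]),
        (ed.inclusion_junctions[0][1], ed.inclusion_junctions[1][0]),
        (ed.inclusion_junctions[1][1], ed.region[1]),
    )
    site_pos = {s.site_label: s.position for s in ed.sites}
    records = []
    for ri in range(n_reads):
        skip = rng.random() < skip_frac
        if skip:
            blocks = [(e1s, e1e), (e3s, e3e)]
            seq = _read_seq(locus.genome, ed.chrom, blocks, rng, 0.0)
        else:
            blocks = [(e1s, e1e), (vbs, vbe), (e3s, e3e)]
            seq = list(_read_seq(locus.genome, ed.chrom, blocks, rng, 0.0))
            haplo = labels[int(rng.choice(len(labels), p=probs))]
            for lab in haplo:
                off = (e1e - e1s) + (site_pos[lab] - vbs)
                seq[off] = "G"
            seq = "".join(seq)
        records.append(
            {
                "qname": f"edit.{ri}",
                "chrom": ed.chrom,
                "pos": e1s,
                "cigar": _blocks_to_cigar(blocks),
                "seq": seq,
                "reverse": False,
            }
        )
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    _write_sam(out_path, locus.genome, records)
    return out_path


def independent_site_haplotypes(marginals: Mapping[str, float]) -> dict[str, float]:
    """Haplotype distribution with independent per-site editing.

    Useful for configuring the generator to hit chosen per-site marginal
    fractions: each of the 2^k site subsets gets the product probability.
    """
    labels = list(marginals)
    dist: dict[str, float] = {"": 1.0}
    for lab in labels:
        p = float(marginals[lab])
        dist = {
            **{combo: q * (1 - p) for combo, q in dist.items()},
            **{combo + lab: q * p for combo, q in dist.items()},
        }
    return dist


def reads_per_gene_for_junction_coverage(
    cfg: SyntheticConfig, locus: LocusSet, coverage: float
) -> int:
    """Reads per gene so each splice boundary sees ~``coverage`` junction reads."""
    w = cfg.read_length - 2 * 8 + 1
    spans = [g.tx_end - g.tx_start for g in locus.genes]
    return int(np.ceil(coverage * max(spans) / w))
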