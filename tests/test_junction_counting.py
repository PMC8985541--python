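"""Junction-read classification, fpkm, and the intergenic background."""

import numpy as np
import pytest

from conftest import make_sam
from riquant.genome_model import GeneModel, IntronRecord
from riquant.junction_counting import (
    background_threshold,
    compute_fpkm,
    count_junctions,
)

INTRON = IntronRecord("gA:200-300", "gA", "c1", "+", 200, 300, 1)
GENE = GeneModel("gA", "c1", "+", 100, 400, [(100, 200), (300, 400)], [[0, 1]])


def _counts(tmp_path, reads, **kw):
    sam = make_sam(tmp_path / "r.sam", reads)
    (c,) = count_junctions(sam, [INTRON], sample_id="s1", **kw)
    return c


def test_exact_gap_with_overhang_is_exon_exon(tmp_path):
    c = _counts(tmp_path, [("r1", "c1", 150, "50M100N50M", "A" * 100, 0)])
    assert (c.EE, c.EI5, c.EI3, c.IB) == (1, 0, 0, 0)


def test_contiguous_read_over_donor_is_ei5_only(tmp_path):
    c = _counts(tmp_path, [("r1", "c1", 192, "50M", "A" * 50, 0)])
    assert (c.EE, c.EI5, c.EI3, c.IB) == (0, 1, 0, 0)


def test_contiguous_read_over_acceptor_is_ei3(tmp_path):
    c = _counts(tmp_path, [("r1", "c1", 292, "50M", "A" * 50, 0)])
    assert (c.EE, c.EI5, c.EI3, c.IB) == (0, 0, 1, 0)


def test_partial_gap_matches_no_category(tmp_path):
    # gap (200,290) over intron (200,300): an alternative junction
    c = _counts(tmp_path, [("r1", "c1", 150, "50M90N50M", "A" * 100, 0)])
    assert (c.EE, c.EI5, c.EI3, c.IB) == (0, 0, 0, 0)


def test_read_inside_intron_is_intronic_body(tmp_path):
    c = _counts(tmp_path, [("r1", "c1", 210, "50M", "A" * 50, 0)])
    assert (c.EE, c.EI5, c.EI3, c.IB) == (0, 0, 0, 1)


def test_insufficient_overhang_rejects_ee_and_ei(tmp_path):
    reads = [
        ("gap", "c1", 195, "5M100N50M", "A" * 55, 0),  # 5 nt left anchor
        ("don", "c1", 195, "10M", "A" * 10, 0),  # covers 195-205 < +/-8 window
    ]
    c = _counts(tmp_path, reads, min_overhang=8)
    assert (c.EE, c.EI5, c.EI3, c.IB) == (0, 0, 0, 0)


def test_antisense_read_excluded_but_in_sense_denominator(tmp_path):
    reads = [
        ("s1r", "c1", 192, "50M", "A" * 50, 0),
        ("a1r", "c1", 192, "50M", "A" * 50, 16),  # wrong strand
    ]
    c = _counts(tmp_path, reads)
    assert c.EI5 == 1
    assert c.sense_fraction == pytest.approx(0.5)


def test_unstranded_mode_counts_both_strands(tmp_path):
    reads = [
        ("s1r", "c1", 192, "50M", "A" * 50, 0),
        ("a1r", "c1", 192, "50M", "A" * 50, 16),
    ]
    c = _counts(tmp_path, reads, library_strand="unstranded")
    assert c.EI5 == 2


def test_mates_merge_with_ee_beating_ei(tmp_path):
    # same qname: one mate EE, one mate IB -> fragment counts once, as EE
    reads = [
        ("frag", "c1", 150, "50M100N50M", "A" * 100, 0x43),   # paired, read1
        ("frag", "c1", 210, "40M", "A" * 40, 0x93),           # paired, read2, reverse
    ]
    c = _counts(tmp_path, reads)
    assert (c.EE, c.EI5, c.EI3, c.IB) == (1, 0, 0, 0)


def test_no_category_double_counting_within_fragment(tmp_path):
    # a read spanning the whole short intron covers both boundary windows:
    # one fragment, one count per category at most
    short = IntronRecord("gB:200-240", "gB", "c1", "+", 200, 240, 1)
    sam = make_sam(tmp_path / "r.sam", [("r1", "c1", 180, "100M", "A" * 100, 0)])
    (c,) = count_junctions(sam, [short], sample_id="s1")
    assert (c.EE, c.EI5, c.EI3, c.IB) == (0, 1, 1, 0)


def test_fpkm_formula_and_proportionality(tmp_path):
    # two genes with 1 kb and 2 kb exonic models, equal read counts
    g1 = GeneModel("g1", "c1", "+", 1000, 2000, [(1000, 2000)], [[0]])
    g2 = GeneModel("g2", "c1", "+", 5000, 7000, [(5000, 7000)], [[0]])
    reads = [(f"a{i}", "c1", 1100 + i, "50M", "A" * 50, 0) for i in range(10)]
    reads += [(f"b{i}", "c1", 5100 + i, "50M", "A" * 50, 0) for i in range(10)]
    sam = make_sam(tmp_path / "f.sam", reads)
    e1, e2 = compute_fpkm(sam, [g1, g2], sample_id="s")
    total_millions = 20 / 1e6
    assert e1.read_count == 10
    assert e1.fpkm == pytest.approx(10 / (1.0 * total_millions))
    assert e1.fpkm / e2.fpkm == pytest.approx(2.0)


def test_gene_without_reads_has_zero_fpkm(tmp_path):
    g1 = GeneModel("g1", "c1", "+", 1000, 2000, [(1000, 2000)], [[0]])
    g2 = GeneModel("g2", "c1", "+", 5000, 6000, [(5000, 6000)], [[0]])
    sam = make_sam(tmp_path / "f.sam", [("a", "c1", 1100, "50M", "A" * 50, 0)])
    e1, e2 = compute_fpkm(sam, [g1, g2], sample_id="s")
    assert e2.read_count == 0 and e2.fpkm == 0.0


def test_zero_mapped_reads_is_an_error(tmp_path):
    sam = make_sam(tmp_path / "e.sam", [("u", "c1", 0, "50M", "A" * 50, 4)])
    with pytest.raises(ValueError, match="zero mapped"):
        compute_fpkm(sam, [GENE], sample_id="s")


def test_background_threshold_zero_when_intergenic_empty(tmp_path):
    g = GeneModel("g1", "c1", "+", 40_000, 41_000, [(40_000, 41_000)], [[0]])
    sam = make_sam(tmp_path / "b.sam", [("a", "c1", 40_100, "50M", "A" * 50, 0)])
    bg = background_threshold(sam, [g], n_regions=100, seed=3, sample_id="s")
    assert bg.intergenic_fpkm_quantile == 0.0


def test_background_threshold_is_deterministic_given_seed(tmp_path):
    g = GeneModel("g1", "c1", "+", 40_000, 41_000, [(40_000, 41_000)], [[0]])
    reads = [("a", "c1", 40_100, "50M", "A" * 50, 0)]
    reads += [(f"i{k}", "c1", 10_000 + 37 * k, "50M", "A" * 50, 0) for k in range(30)]
    sam = make_sam(tmp_path / "b.sam", reads)
    t1 = background_threshold(sam, [g], n_regions=150, seed=7, sample_id="s")
    t2 = background_threshold(sam, [g], n_regions=150, seed=7, sample_id="s")
    assert t1.intergenic_fpkm_quantile == t2.intergenic_fpkm_quantile


def test_percentile_convention_on_spec_vector():
    """95 zeros + [1..5]: order-statistic interpolation lands in [0.75, 1.0]."""
    values = np.array([0.0] * 95 + [1, 2, 3, 4, 5])
    thr = float(np.percentile(values, 95, method="weibull"))
    assert 0.75 <= thr <= 1.0


def test_ei_fraction_tracks_retention_on_synthetic_reads(
    small_cfg, small_locus, short_read_paths
):
    """EI5/(EI5+EE) converges to the true retention fraction rho."""
    counts = count_junctions(
        short_read_paths["AI_rep1"], small_locus.introns, sample_id="AI_rep1"
    )
    rho = small_locus.truth.rho["AI"]
    for c in counts:
        n = c.EI5 + c.EE
        if n < 20:
            continue
        p = rho[c.intron_id]
        se = np.sqrt(max(p * (1 - p), 1e-12) / n)
        assert abs(c.EI5 / n - p) <= max(3 * se, 2 / n)


def test_sense_fraction_matches_strandedness(small_locus, short_read_paths):
    counts = count_junctions(
        short_read_paths["AN_rep1"], small_locus.introns, sample_id="AN_rep1"
    )
    fracs = [c.sense_fraction for c in counts if not np.isnan(c.sense_fraction)]
    assert np.average(fracs) >= 0.96
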