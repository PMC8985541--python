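"""Generator guarantees: construction invariants, determinism, edge cases."""

import filecmp

import numpy as np
import pysam
import pytest

from riquant.junction_counting import count_junctions
from riquant.longread_validation import classify_alignments
from riquant.ri_detection import pooled_pir
from riquant.editing_analysis import site_editing
from riquant.synthetic_data import (
    SyntheticConfig,
    make_locus_set,
    simulate_editing_reads,
    simulate_long_reads,
    simulate_short_reads,
)


def test_all_introns_begin_gt_and_end_ag(small_locus):
    for i in small_locus.introns:
        s = small_locus.genome.fetch(i.chrom, i.start, i.end, i.strand)
        assert s[:2] == "GT" and s[-2:] == "AG"


def test_gene_spacing_leaves_intergenic_room(small_locus, small_cfg):
    spans = sorted((g.tx_start, g.tx_end) for g in small_locus.genes)
    for (_, e1), (s2, _) in zip(spans, spans[1:]):
        assert s2 - e1 >= small_cfg.intergenic_spacer


def test_seed_mandatory_and_rho_validated():
    with pytest.raises(TypeError):
        SyntheticConfig()  # seed is required
    with pytest.raises(ValueError):
        SyntheticConfig(seed=1, rho_retained=1.5)


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = SyntheticConfig(seed=33, n_genes=3, reads_per_gene=50, longread_depth=5)
    for d in ("a", "b"):
        locus = make_locus_set(cfg)
        out = tmp_path / d
        locus.write(out)
        simulate_short_reads(cfg, locus, out / "sr")
        simulate_long_reads(cfg, locus, out / "lr")
        simulate_editing_reads(cfg, locus, out / "edit.sam")
    files = sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*") if p.is_file())
    assert files
    for rel in files:
        assert filecmp.cmp(tmp_path / "a" / rel, tmp_path / "b" / rel, shallow=False), rel


def test_truth_table_consistent_with_config(small_locus, small_cfg):
    rho = small_locus.truth.rho
    assert set(rho.columns) == set(small_cfg.conditions)
    assert ((rho.values == small_cfg.rho_background) | (rho.values == small_cfg.rho_retained)).all()
    exp = small_locus.truth.expected_retained()
    assert (exp == (100 * rho > 25)).all().all()


def test_zero_retention_yields_no_exon_intron_reads(tmp_path):
    cfg = SyntheticConfig(
        seed=5, n_genes=2, reads_per_gene=300, error_rate=0.0,
        frac_retained_introns=0.0, rho_background=0.0, editing_enabled=False,
    )
    locus = make_locus_set(cfg)
    paths = simulate_short_reads(cfg, locus, tmp_path)
    counts = count_junctions(paths["AI_rep1"], locus.introns, sample_id="s")
    assert all(c.EI5 == 0 and c.EI3 == 0 and c.IB == 0 for c in counts)
    assert all(c.EE > 0 for c in counts)


def test_full_retention_yields_no_exon_exon_reads(tmp_path):
    cfg = SyntheticConfig(
        seed=5, n_genes=2, reads_per_gene=300, error_rate=0.0,
        frac_retained_introns=1.0, frac_condition_specific=0.0,
        rho_retained=1.0, editing_enabled=False,
    )
    locus = make_locus_set(cfg)
    paths = simulate_short_reads(cfg, locus, tmp_path)
    counts = count_junctions(paths["AI_rep1"], locus.introns, sample_id="s")
    assert all(c.EE == 0 for c in counts)
    assert any(c.EI5 > 0 for c in counts)


def test_pooled_minpir_recovers_rho_within_binomial_error(tmp_path):
    cfg = SyntheticConfig(
        seed=8, n_genes=2, reads_per_gene=800, error_rate=0.0,
        frac_retained_introns=0.0, editing_enabled=False,
    )
    locus = make_locus_set(cfg)
    locus.truth.rho.loc[:, :] = 0.3
    paths = simulate_short_reads(cfg, locus, tmp_path)
    by_rep = {
        s: count_junctions(paths[s], locus.introns, sample_id=s)
        for s in ("AI_rep1", "AI_rep2", "AI_rep3")
    }
    for iid in locus.truth.rho.index:
        reps = [next(c for c in cs if c.intron_id == iid) for cs in by_rep.values()]
        est = pooled_pir(reps)
        n = min(
            sum(c.EI5 + c.EE for c in reps), sum(c.EI3 + c.EE for c in reps)
        )
        se = 100 * np.sqrt(0.3 * 0.7 / n)
        assert abs(est.minPIR - 30.0) <= 3 * se + 1e-9


def test_long_reads_fully_retained_without_noise(tmp_path):
    cfg = SyntheticConfig(
        seed=6, n_genes=2, longread_depth=15, lr_truncation_prob=0.0,
        lr_indel_rate=0.0, frac_retained_introns=1.0, frac_condition_specific=0.0,
        rho_retained=1.0, editing_enabled=False,
    )
    locus = make_locus_set(cfg)
    paths = simulate_long_reads(cfg, locus, tmp_path)
    calls = classify_alignments(paths["AI"], locus.introns)
    assert calls and all(c.verdict == "retained" for c in calls)


def test_long_read_retained_fraction_tracks_rho(tmp_path):
    cfg = SyntheticConfig(
        seed=7, n_genes=3, longread_depth=40, lr_truncation_prob=0.0,
        lr_indel_rate=0.0, frac_retained_introns=0.0, editing_enabled=False,
    )
    locus = make_locus_set(cfg)
    locus.truth.rho.loc[:, :] = 0.5
    paths = simulate_long_reads(cfg, locus, tmp_path)
    calls = classify_alignments(paths["AI"], locus.introns)
    informative = [c for c in calls if c.verdict != "uninformative"]
    frac = np.mean([c.verdict == "retained" for c in informative])
    se = np.sqrt(0.25 / len(informative))
    assert abs(frac - 0.5) <= 3 * se


def test_editing_reads_obey_degenerate_distributions(tmp_path):
    cfg = SyntheticConfig(seed=9, n_genes=2, editing_reads=200)
    locus = make_locus_set(cfg)
    none = simulate_editing_reads(
        cfg, locus, tmp_path / "none.sam", haplotypes={"": 1.0}, skipping_fraction=0.0
    )
    assert all(
        r.editing_fraction == 0.0 for r in site_editing(none, locus.editing.sites)
    )
    full = simulate_editing_reads(
        cfg, locus, tmp_path / "full.sam",
        haplotypes={"ABCDE": 1.0}, skipping_fraction=0.0,
    )
    assert all(
        r.editing_fraction == 1.0 for r in site_editing(full, locus.editing.sites)
    )


def test_short_reads_are_valid_sam_with_expected_length(short_read_paths, small_cfg):
    af = pysam.AlignmentFile(str(short_read_paths["BN_rep2"]), check_sq=False)
    n = 0
    for read in af:
        n += 1
        assert read.query_length == small_cfg.read_length
        assert read.cigartuples[0][0] == 0 and read.cigartuples[-1][0] == 0
    assert n == small_cfg.n_genes * small_cfg.reads_per_gene
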