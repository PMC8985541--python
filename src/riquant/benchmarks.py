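"""Property benchmarks: simulation-based recovery checks for every stage.

Each function regenerates its inputs from a seed, runs the pipeline, and
returns measured quantities (recovery errors, recall rates, test power...).
The test suite asserts the corresponding bounds; the reproduction script
reports the numbers.  Problem sizes follow the emulated study design:
4 conditions x 3 replicates, 150 nt strand-specific reads, ~100x junction
coverage for recovery checks, 20x long-read depth, 500-1000 editing reads.
"""

from __future__ import annotations

import filecmp
import itertools
import math
import re
import tempfile
from pathlib import Path

import numpy as np

from .editing_analysis import (
    SiteEditingResult,
    compare_site_editing,
    exon_skipping,
    haplotype_table,
    site_editing,
)
from .junction_counting import (
    background_threshold,
    compute_fpkm,
    count_junctions,
    counts_to_frame,
)
from .longread_validation import classify_alignments, validate_candidates
from .ri_detection import RiCallConfig, call_retained, compute_pir, pir_frame, pooled_pir
from .ri_differential import is_switched, splicing_index
from .ri_features import stop_codon_frames
from .synthetic_data import (
    SyntheticConfig,
    independent_site_haplotypes,
    make_locus_set,
    reads_per_gene_for_junction_coverage,
    simulate_editing_reads,
    simulate_long_reads,
    simulate_short_reads,
)

PIR_RHO_GRID = (0.0, 0.1, 0.3, 0.6, 1.0)


def pir_recovery(seed: int, coverage: int = 100, workdir=None) -> dict:
    """Pooled minPIR vs true retention on a rho grid at ~``coverage``x.

    One gene per rho value; reads are generated so each splice boundary
    sees about ``coverage`` junction reads.  Error bands are 3 binomial
    standard errors on the smaller boundary denominator.
    """
    cfg = SyntheticConfig(
        seed=seed,
        n_genes=len(PIR_RHO_GRID),
        conditions=("C1",),
        replicates=1,
        error_rate=0.0,
        frac_retained_introns=0.0,
        editing_enabled=False,
    )
    locus = make_locus_set(cfg)
    cfg = SyntheticConfig(
        **{
            **cfg.__dict__,
            "reads_per_gene": reads_per_gene_for_junction_coverage(cfg, locus, coverage),
        }
    )
    for gene, rho in zip(locus.genes, PIR_RHO_GRID):
        locus.truth.rho.loc[locus.layouts[gene.gene_id].intron_ids, :] = rho
    with tempfile.TemporaryDirectory(dir=workdir) as td:
        paths = simulate_short_reads(cfg, locus, td)
        counts = count_junctions(paths["C1_rep1"], locus.introns, sample_id="C1_rep1")
    rho_truth = locus.truth.rho["C1"]
    max_abs = 0.0
    max_se_units = 0.0
    n_junction = 0
    all_within = True
    for c in counts:
        est = compute_pir(c)
        rho = float(rho_truth[c.intron_id])
        n = min(c.EI5 + c.EE, c.EI3 + c.EE)
        n_junction += c.EE + c.EI5 + c.EI3
        err = abs(est.minPIR - 100.0 * rho)
        se = 100.0 * math.sqrt(rho * (1 - rho) / n)
        max_abs = max(max_abs, err)
        if se > 0:
            max_se_units = max(max_se_units, err / se)
            all_within &= err <= 3 * se
        else:
            all_within &= err == 0.0
    return {
        "max_abs_error_pct": max_abs,
        "max_error_se_units": max_se_units,
        "all_within_3se": all_within,
        "n": n_junction,
    }


def ri_calling(seed: int, n_genes: int = 50, reads_per_gene: int = 250, workdir=None) -> dict:
    """Recall / false-call rate of the full filter chain on generator truth.

    minPIR > 25 in more than half of 3 replicates, >= 10 junction reads,
    host gene above the 95th-percentile intergenic background — per
    condition, against the truth table (rho_retained = 0.5 vs
    rho_background = 0.02).
    """
    cfg = SyntheticConfig(
        seed=seed, n_genes=n_genes, reads_per_gene=reads_per_gene, editing_enabled=False
    )
    locus = make_locus_set(cfg)
    intron_gene = {i.intron_id: i.gene_id for i in locus.introns}
    with tempfile.TemporaryDirectory(dir=workdir) as td:
        paths = simulate_short_reads(cfg, locus, td)
        counts, expr, bg, sense = {}, {}, {}, []
        for s, p in paths.items():
            counts[s] = count_junctions(p, locus.introns, sample_id=s)
            expr[s] = {e.gene_id: e.fpkm for e in compute_fpkm(p, locus.genes, sample_id=s)}
            bg[s] = background_threshold(p, locus.genes, n_regions=200, seed=seed, sample_id=s)
            sense.extend(
                c.sense_fraction for c in counts[s] if not math.isnan(c.sense_fraction)
            )
    expected = locus.truth.expected_retained()
    tp = fn = fp = tn = 0
    for cond in cfg.conditions:
        reps = {s: counts[s] for s in counts if s.startswith(cond)}
        ex = {s: expr[s] for s in reps}
        b = {s: bg[s] for s in reps}
        for call in call_retained(reps, ex, b, intron_gene, cond, RiCallConfig()):
            truth = bool(expected.loc[call.intron_id, cond])
            if truth:
                tp += call.retained
                fn += not call.retained
            else:
                fp += call.retained
                tn += not call.retained
    return {
        "recall": tp / (tp + fn),
        "false_call_rate": fp / (fp + tn),
        "mean_sense_fraction": float(np.mean(sense)),
        "n": tp + fn + fp + tn,
    }


def switch_rule_grid() -> dict:
    """Exhaustive integer PIR grid vs a literal transcription of the rule."""

    def sentence(a: float, b: float) -> bool:
        # "intron usage of lesser or equal than 25% in one condition and
        #  more than 25% in the other condition"
        return (a <= 25 and b > 25) or (b <= 25 and a > 25)

    n = agree = 0
    for a, b in itertools.product(range(101), repeat=2):
        n += 1
        agree += is_switched(float(a), float(b)) == sentence(a, b)
    return {"agreement": agree / n, "n": n}


def longread_validation(
    seed: int, n_true: int = 50, n_false: int = 50, depth: int = 20, workdir=None
) -> dict:
    """Validation rates for true retained introns (rho = 0.5) vs candidates
    with no retention (rho = 0), at the given long-read depth."""
    cfg = SyntheticConfig(
        seed=seed,
        n_genes=32,
        exons_per_gene=(4, 6),
        conditions=("C1",),
        longread_depth=depth,
        frac_retained_introns=0.0,
        rho_background=0.0,
        editing_enabled=False,
    )
    locus = make_locus_set(cfg)
    ids = [i.intron_id for i in locus.introns]
    if len(ids) < n_true + n_false:
        raise ValueError("locus too small for requested candidate counts")
    true_ids, false_ids = ids[:n_true], ids[n_true : n_true + n_false]
    locus.truth.rho.loc[true_ids, :] = 0.5
    locus.truth.rho.loc[false_ids, :] = 0.0
    with tempfile.TemporaryDirectory(dir=workdir) as td:
        paths = simulate_long_reads(cfg, locus, td)
        wanted = set(true_ids) | set(false_ids)
        calls = classify_alignments(
            paths["C1"], [i for i in locus.introns if i.intron_id in wanted]
        )
    _, rate_true, _ = validate_candidates(calls, true_ids, min_support=1)
    _, rate_false, _ = validate_candidates(calls, false_ids, min_support=1)
    return {
        "true_validation_rate": rate_true,
        "false_validation_rate": rate_false,
        "n": n_true + n_false,
    }


def stop_codon_agreement(seed: int, max_len: int = 12, n_random: int = 1000) -> dict:
    """Exact agreement with an independent regex scanner: exhaustive over
    all sequences up to ``max_len`` plus random 1 kb sequences."""
    pat = re.compile(r"(?=(TAA|TAG|TGA))")

    def oracle(s: str) -> set[int]:
        return {m.start() % 3 for m in pat.finditer(s)}

    n = agree = 0
    for L in range(1, max_len + 1):
        for tup in itertools.product("ACGT", repeat=L):
            s = "".join(tup)
            n += 1
            agree += stop_codon_frames(s) == oracle(s)
    rng = np.random.default_rng(seed)
    all_frames = 0
    for _ in range(n_random):
        s = "".join(rng.choice(list("ACGT"), size=1000))
        n += 1
        frames = stop_codon_frames(s)
        agree += frames == oracle(s)
        all_frames += frames == {0, 1, 2}
    return {
        "agreement": agree / n,
        "random_1kb_all_frames_fraction": all_frames / n_random,
        "n": n,
    }


EDITING_TRUE_MARGINALS = {"A": 0.8, "B": 0.6, "C": 0.1, "D": 0.4, "E": 0.05}


def editing_recovery(
    seed: int, n_reads: int = 1000, n_null_sims: int = 500, workdir=None
) -> dict:
    """Per-site and haplotype recovery plus null behaviour of the
    between-condition comparison.

    Reads are generated with independent per-site editing at the configured
    marginals and 25% exon skipping; the null type-I rate feeds identical
    per-site tallies (binomial draws at the same marginals, 500 reads per
    condition) to the two-proportion comparison.
    """
    cfg = SyntheticConfig(
        seed=seed,
        n_genes=2,
        editing_reads=n_reads,
        editing_haplotypes=independent_site_haplotypes(EDITING_TRUE_MARGINALS),
        skipping_fraction=0.25,
    )
    locus = make_locus_set(cfg)
    with tempfile.TemporaryDirectory(dir=workdir) as td:
        sam = simulate_editing_reads(cfg, locus, Path(td) / "edit.sam")
        sites = locus.editing.sites
        site_res = site_editing(sam, sites)
        table = haplotype_table(sam, sites)
        informative = site_editing(sam, sites, require_all_sites=True)
        skip = exon_skipping(
            sam, locus.editing.inclusion_junctions, locus.editing.skipping_junction
        )

    n_info = table.total
    max_site_se = 0.0
    max_site_abs = 0.0
    for r in site_res:
        p = EDITING_TRUE_MARGINALS[r.site_label]
        nn = r.n_ref + r.n_edited
        err = abs(r.editing_fraction - p)
        se = math.sqrt(p * (1 - p) / nn) if 0 < p < 1 else 0.0
        max_site_abs = max(max_site_abs, err)
        if se > 0:
            max_site_se = max(max_site_se, err / se)
        else:
            max_site_se = max(max_site_se, 0.0 if err == 0 else math.inf)

    expected_hap = independent_site_haplotypes(EDITING_TRUE_MARGINALS)
    max_hap_se = 0.0
    pct = table.percents()
    for combo, p in expected_hap.items():
        obs = pct.get(combo, 0.0) / 100.0
        se = math.sqrt(p * (1 - p) / n_info) if 0 < p < 1 else 0.0
        if se > 0:
            max_hap_se = max(max_hap_se, abs(obs - p) / se)
        elif obs != p:
            max_hap_se = math.inf

    marg = table.marginal_fractions(list(EDITING_TRUE_MARGINALS))
    info_frac = {r.site_label: r.editing_fraction for r in informative}
    marginal_gap = max(abs(marg[lab] - info_frac[lab]) for lab in marg)

    p_skip = cfg.skipping_fraction
    skip_se = math.sqrt(
        p_skip * (1 - p_skip) / (skip.n_inclusion_junctions + skip.n_skipping_junctions)
    )
    skip_se_units = abs(skip.skipping_fraction - p_skip) / skip_se

    rng = np.random.default_rng([seed, 99])
    n_cond = 500
    rejections = total = 0
    for _ in range(n_null_sims):
        res = []
        for _cond in range(2):
            res.append(
                [
                    SiteEditingResult(
                        "x", lab, int(n_cond - k), int(k), 0
                    )
                    for lab, k in (
                        (lab, rng.binomial(n_cond, p))
                        for lab, p in EDITING_TRUE_MARGINALS.items()
                    )
                ]
            )
        for comp in compare_site_editing(res[0], res[1]):
            total += 1
            rejections += comp.p_value <= 0.05
    return {
        "max_site_error_se_units": max_site_se,
        "max_site_error_abs": max_site_abs,
        "max_haplotype_error_se_units": max_hap_se,
        "marginal_equality_gap": marginal_gap,
        "skipping_error_se_units": skip_se_units,
        "null_type1_rate": rejections / total,
        "n": n_info,
    }


def splicing_index_performance(seed: int, n_sims: int = 200, cv: float = 0.10) -> dict:
    """Monte-Carlo power (true FC 3, EXON-style flags) and size at alpha=0.05
    of the splicing-index test, 3 vs 3 replicates, 10% coefficient of variation."""
    rng = np.random.default_rng([seed, 7])
    sigma = math.sqrt(math.log(1 + cv**2))
    gene = 10_000.0

    def draw(mean_inc):
        inc = mean_inc * rng.lognormal(-sigma**2 / 2, sigma, size=3)
        return inc * gene

    power_hits = 0
    null_rejects = 0
    for _ in range(n_sims):
        res = splicing_index(draw(0.10), [gene] * 3, draw(0.30), [gene] * 3)
        power_hits += res.significant_exon
        null = splicing_index(draw(0.10), [gene] * 3, draw(0.10), [gene] * 3)
        null_rejects += null.p_value <= 0.05
    return {
        "power_fc3": power_hits / n_sims,
        "type1_rate": null_rejects / n_sims,
        "n": n_sims,
    }


def determinism(seed: int, workdir=None) -> dict:
    """Byte-identity of every generated and derived output over two runs."""
    cfg = SyntheticConfig(
        seed=seed, n_genes=4, reads_per_gene=100, longread_depth=8, editing_reads=200
    )

    def run(out: Path) -> None:
        locus = make_locus_set(cfg)
        locus.write(out)
        srs = simulate_short_reads(cfg, locus, out / "sr")
        simulate_long_reads(cfg, locus, out / "lr")
        simulate_editing_reads(cfg, locus, out / "edit.sam")
        sample = sorted(srs)[0]
        counts = count_junctions(srs[sample], locus.introns, sample_id=sample)
        counts_to_frame(counts).round(6).to_csv(out / "counts.tsv", sep="\t", index=False)
        pir_frame([compute_pir(c) for c in counts]).round(6).to_csv(
            out / "pir.tsv", sep="\t", index=False
        )

    with tempfile.TemporaryDirectory(dir=workdir) as td:
        a, b = Path(td) / "a", Path(td) / "b"
        run(a)
        run(b)
        files = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        identical = bool(files) and all(
            filecmp.cmp(a / rel, b / rel, shallow=False) for rel in files
        )
        return {"identical": identical, "n": len(files)}
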