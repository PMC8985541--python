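"""Differential retained-intron switches and splicing-index tests.

Switch calling is categorical: an intron switches between two conditions
when its pooled intron usage is <= 25% in one condition and > 25% in the
other, with the host gene expressed in both.  The splicing-index test
compares per-replicate normalized inclusion (feature reads / gene reads)
between conditions with a Welch test on log2 inclusion; PATTERN-style
significance needs p <= 0.05 and fold change >= 1.5, EXON-style needs
p <= 0.01 and fold change >= 2.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

SWITCH_THRESHOLD = 25.0
PATTERN_P, PATTERN_FC = 0.05, 1.5
EXON_P, EXON_FC = 0.01, 2.0
DE_P, DE_FC = 0.05, 1.5

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_CV_FLOOR = 0.05


@dataclass
class RiSwitch:
    intron_id: str
    condition_a: str
    condition_b: str
    pir_a: float
    pir_b: float
    switched: bool
    direction: str  # "up_in_b" | "down_in_b" | "none"


@dataclass
class SplicingIndexResult:
    feature_id: str
    fold_change: float
    p_value: float
    significant_pattern: bool
    significant_exon: bool
    p_adj: float = float("nan")


@dataclass
class DiffExprResult:
    gene_id: str
    fold_change: float
    p_value: float
    significant: bool
    p_adj: float = float("nan")
    method: str = "welch-log2-cpm (simplified stand-in for count-model DE)"


def is_switched(pir_a: float, pir_b: float, threshold: float = SWITCH_THRESHOLD) -> bool:
    """The categorical switch rule: <= threshold on one side, > on the other."""
    return (pir_a <= threshold and pir_b > threshold) or (
        pir_a > threshold and pir_b <= threshold
    )


def call_switches(
    pir_a: Mapping[str, float],
    pir_b: Mapping[str, float],
    condition_a: str,
    condition_b: str,
    expressed_a: Mapping[str, bool] | None = None,
    expressed_b: Mapping[str, bool] | None = None,
    threshold: float = SWITCH_THRESHOLD,
    tally: dict | None = None,
) -> list[RiSwitch]:
    """Switch calls over the shared intron universe of two conditions.

    ``pir_*`` map intron_id to pooled condition-level PIR (NaN = undefined).
    Introns undefined in either condition are excluded and tallied.
    """
    universe = sorted(set(pir_a) & set(pir_b))
    if not universe:
        raise ValueError("conditions share no introns (disjoint universes)")
    tally = tally if tally is not None else {}
    tally.setdefault("excluded_undefined", 0)
    tally.setdefault("excluded_not_expressed", 0)
    out = []
    for iid in universe:
        a, b = pir_a[iid], pir_b[iid]
        if math.isnan(a) or math.isnan(b):
            tally["excluded_undefined"] += 1
            continue
        if expressed_a is not None and not (
            expressed_a.get(iid, False) and (expressed_b or {}).get(iid, False)
        ):
            tally["excluded_not_expressed"] += 1
            continue
        sw = is_switched(a, b, threshold)
        direction = "none"
        if sw:
            direction = "up_in_b" if b > a else "down_in_b"
        out.append(RiSwitch(iid, condition_a, condition_b, a, b, sw, direction))
    return out


def welch_test(
    x: Sequence[float], y: Sequence[float], var_floor: float = 0.0
) -> tuple[float, float]:
    """Welch two-sample t-test with a per-group variance floor.

    Returns (t, two-sided p).  The floor keeps the test defined when a group
    has zero sample variance (e.g. exactly replicated toy inputs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("welch_test needs >= 2 observations per group")
    vx = max(float(np.var(x, ddof=1)), var_floor)
    vy = max(float(np.var(y, ddof=1)), var_floor)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return 0.0, 1.0
    t = (float(np.mean(y)) - float(np.mean(x))) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, p


def _log2_var_floor(cv_floor: float) -> float:
    # delta method: a CV floor on the linear scale maps to a constant
    # variance floor (cv/ln 2)^2 on the log2 scale
    return (cv_floor / math.log(2)) ** 2


def splicing_index(
    feature_a: Sequence[float],
    gene_a: Sequence[float],
    feature_b: Sequence[float],
    gene_b: Sequence[float],
    feature_id: str = "feature",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    cv_floor: float = DEFAULT_CV_FLOOR,
) -> SplicingIndexResult:
    """Differential inclusion of a feature (exon or intron) within its gene.

    Normalized inclusion per replicate = (feature + pc) / (gene + pc); the
    fold change is the ratio of condition means (reported as max(r, 1/r) vs
    the thresholds) and the p-value comes from a Welch test on log2
    inclusion with a variance floor.
    """
    ga = np.asarray(gene_a, dtype=float)
    gb = np.asarray(gene_b, dtype=float)
    if np.any(ga <= 0) or np.any(gb <= 0):
        raise ValueError(f"{feature_id}: gene count 0 in a replicate; feature skipped")
    inc_a = (np.asarray(feature_a, dtype=float) + pseudocount) / (ga + pseudocount)
    inc_b = (np.asarray(feature_b, dtype=float) + pseudocount) / (gb + pseudocount)
    fc = float(np.mean(inc_b) / np.mean(inc_a))
    _, p = welch_test(np.log2(inc_a), np.log2(inc_b), _log2_var_floor(cv_floor))
    mag = max(fc, 1.0 / fc)
    return SplicingIndexResult(
        feature_id=feature_id,
        fold_change=fc,
        p_value=p,
        significant_pattern=(p <= PATTERN_P and mag >= PATTERN_FC),
        significant_exon=(p <= EXON_P and mag >= EXON_FC),
    )


def gene_de(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    lib_a: Sequence[float],
    lib_b: Sequence[float],
    gene_ids: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    cv_floor: float = DEFAULT_CV_FLOOR,
) -> list[DiffExprResult]:
    """Two-condition differential expression on library-size-normalized counts.

    A deliberately simple Welch test on log2 CPM with FC >= 1.5 and
    uncorrected p <= 0.05 flags, plus a BH-adjusted column for reference.
    This is a self-contained simplification, labelled as such in each
    record's ``method`` field; it is not a negative-binomial count model.
    Genes absent in all samples are excluded.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    cpm_a = (counts_a + pseudocount) / np.asarray(lib_a, dtype=float)[None, :] * 1e6
    cpm_b = (counts_b + pseudocount) / np.asarray(lib_b, dtype=float)[None, :] * 1e6
    floor = _log2_var_floor(cv_floor)
    results = []
    for gi, gene in enumerate(gene_ids):
        if counts_a[gi].sum() == 0 and counts_b[gi].sum() == 0:
            continue
        fc = float(np.mean(cpm_b[gi]) / np.mean(cpm_a[gi]))
        _, p = welch_test(np.log2(cpm_a[gi]), np.log2(cpm_b[gi]), floor)
        mag = max(fc, 1.0 / fc)
        results.append(
            DiffExprResult(gene, fc, p, bool(p <= DE_P and mag >= DE_FC))
        )
    if results:
        padj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, padj):
            r.p_adj = float(q)
    return results
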