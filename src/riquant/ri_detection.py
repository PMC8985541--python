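"""PIR / minPIR computation and condition-level retained-intron calling.

The per-boundary statistic is PIR (percent intron retention),
``100 * EI / (EI + EE)``; minPIR is the minimum over the two boundaries —
the conservative statistic that lets one clean boundary veto.  An intron is
called retained in a condition when minPIR exceeds the threshold (default
strictly > 25) in more than half of the biological replicates and the host
gene is expressed above the intergenic background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .junction_counting import BackgroundModel, GeneExpression, JunctionCounts


@dataclass
class PirEstimate:
    sample_id: str
    intron_id: str
    PIR5: float
    PIR3: float
    minPIR: float
    coverage: int
    defined: bool


@dataclass
class RiCallConfig:
    pir_threshold: float = 25.0        # strict inequality, percent
    replicate_fraction: float = 0.5    # strict inequality
    min_coverage: int = 10             # junction reads (EE+EI5+EI3)
    require_gene_expressed: bool = True
    pir_mode: str = "junctions"        # or "with_intronic"
    read_length: int = 150
    min_overhang: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.pir_threshold < 100:
            raise ValueError("pir_threshold must be in (0, 100)")
        if self.pir_mode not in ("junctions", "with_intronic"):
            raise ValueError(f"unknown pir_mode: {self.pir_mode}")


@dataclass
class RiCall:
    condition_id: str
    intron_id: str
    retained: bool
    n_replicates_passing: int
    n_replicates: int
    pooled_minPIR: float
    novel: bool = True
    status: str = "ok"  # "ok" or "no_data"


def _ib_junction_equivalent(
    ib: float, intron_length: int | None, read_length: int, min_overhang: int
) -> float:
    """Intronic-body reads rescaled to junction-equivalent counts.

    The number of start positions yielding a boundary-window read is
    ``read_length - 2*overhang + 1``; the number yielding an intron-contained
    read is ``intron_length - read_length + 1``.  Their ratio converts an IB
    tally into the count a single junction window would have seen.
    """
    if intron_length is None:
        raise ValueError("pir_mode='with_intronic' requires intron_length")
    w_junction = max(read_length - 2 * min_overhang + 1, 1)
    w_body = max(intron_length - read_length + 1, 1)
    return ib * w_junction / w_body


def compute_pir(
    counts: JunctionCounts,
    pir_mode: str = "junctions",
    intron_length: int | None = None,
    read_length: int = 150,
    min_overhang: int = 8,
) -> PirEstimate:
    """PIR per boundary and minPIR for one intron in one sample.

    Total function: never raises on count values; ``defined`` is False when
    either boundary denominator is zero.
    """
    ee, ei5, ei3 = counts.EE, counts.EI5, counts.EI3
    extra = 0.0
    if pir_mode == "with_intronic":
        extra = _ib_junction_equivalent(counts.IB, intron_length, read_length, min_overhang)
    num5, num3 = ei5 + extra, ei3 + extra
    den5, den3 = num5 + ee, num3 + ee
    defined = den5 > 0 and den3 > 0
    pir5 = 100.0 * num5 / den5 if den5 > 0 else float("nan")
    pir3 = 100.0 * num3 / den3 if den3 > 0 else float("nan")
    minpir = min(pir5, pir3) if defined else float("nan")
    return PirEstimate(
        sample_id=counts.sample_id,
        intron_id=counts.intron_id,
        PIR5=pir5,
        PIR3=pir3,
        minPIR=minpir,
        coverage=ee + ei5 + ei3,
        defined=defined,
    )


def pooled_pir(
    counts: Sequence[JunctionCounts],
    pir_mode: str = "junctions",
    intron_length: int | None = None,
    read_length: int = 150,
    min_overhang: int = 8,
) -> PirEstimate:
    """Condition-level PIR from counts summed over replicates (sum then ratio)."""
    if not counts:
        raise ValueError("pooled_pir needs at least one replicate")
    iid = counts[0].intron_id
    if any(c.intron_id != iid for c in counts):
        raise ValueError("pooled_pir mixes introns")
    total = JunctionCounts(
        sample_id="pooled",
        intron_id=iid,
        EE=sum(c.EE for c in counts),
        EI5=sum(c.EI5 for c in counts),
        EI3=sum(c.EI3 for c in counts),
        IB=sum(c.IB for c in counts),
    )
    return compute_pir(total, pir_mode, intron_length, read_length, min_overhang)


def call_retained(
    counts_by_replicate: Mapping[str, Sequence[JunctionCounts]],
    expression: Mapping[str, Mapping[str, float]],
    background: Mapping[str, float | BackgroundModel],
    intron_gene: Mapping[str, str],
    condition_id: str,
    cfg: RiCallConfig | None = None,
    known_retained: Mapping[str, bool] | None = None,
    intron_lengths: Mapping[str, int] | None = None,
    replicate_rule: str = "pir_filter",
) -> list[RiCall]:
    """Call retained introns for one condition.

    Parameters
    ----------
    counts_by_replicate
        sample_id -> junction counts for every intron in that replicate.
    expression
        sample_id -> {gene_id -> fpkm}.
    background
        sample_id -> intergenic background threshold (or BackgroundModel).
    replicate_rule
        "pir_filter" (a replicate passes when defined, covered and
        minPIR > threshold) or "any_evidence" (>=1 intronic/EI read).
    """
    cfg = cfg or RiCallConfig()
    samples = sorted(counts_by_replicate)
    if len(samples) < 2:
        raise ValueError("call_retained requires >= 2 replicates")
    bg = {
        s: (b.intergenic_fpkm_quantile if isinstance(b, BackgroundModel) else float(b))
        for s, b in background.items()
    }

    per_intron: dict[str, dict[str, JunctionCounts]] = {}
    for s in samples:
        for c in counts_by_replicate[s]:
            per_intron.setdefault(c.intron_id, {})[s] = c

    calls = []
    for iid in sorted(per_intron):
        reps = per_intron[iid]
        gene = intron_gene[iid]
        ilen = intron_lengths.get(iid) if intron_lengths else None
        n_pass = 0
        n_defined = 0
        for s in samples:
            c = reps.get(s)
            if c is None:
                continue
            est = compute_pir(c, cfg.pir_mode, ilen, cfg.read_length, cfg.min_overhang)
            if est.defined:
                n_defined += 1
            if replicate_rule == "any_evidence":
                if c.EI5 + c.EI3 + c.IB >= 1:
                    n_pass += 1
            else:
                if (
                    est.defined
                    and est.coverage >= cfg.min_coverage
                    and est.minPIR > cfg.pir_threshold
                ):
                    n_pass += 1
        pooled = pooled_pir(
            [reps[s] for s in samples if s in reps],
            cfg.pir_mode,
            ilen,
            cfg.read_length,
            cfg.min_overhang,
        )
        expressed = True
        if cfg.require_gene_expressed:
            n_expr = sum(
                1
                for s in samples
                if expression[s].get(gene, 0.0) > bg[s]
            )
            expressed = n_expr / len(samples) > 0.5
        if n_defined == 0:
            calls.append(
                RiCall(condition_id, iid, False, 0, len(samples), float("nan"),
                       not (known_retained or {}).get(iid, False), "no_data")
            )
            continue
        retained = (n_pass / len(samples) > cfg.replicate_fraction) and expressed
        calls.append(
            RiCall(
                condition_id,
                iid,
                retained,
                n_pass,
                len(samples),
                pooled.minPIR,
                not (known_retained or {}).get(iid, False),
                "ok",
            )
        )
    return calls


def novel_ri_census(calls_by_condition: Mapping[str, Sequence[RiCall]]):
    """Presence/absence of retained calls across conditions plus Venn counts.

    Returns ``(presence, regions)``: a boolean DataFrame (introns x
    conditions, restricted to introns retained somewhere) and a Series of
    counts per Venn region keyed by the tuple of conditions in which the
    intron is retained.
    """
    conditions = sorted(calls_by_condition)
    if not conditions:
        raise ValueError("census needs at least one condition")
    for cond in conditions:
        if not calls_by_condition[cond]:
            raise ValueError(f"condition {cond} has no calls")
    rows: dict[str, dict[str, bool]] = {}
    novel: dict[str, bool] = {}
    for cond in conditions:
        for call in calls_by_condition[cond]:
            rows.setdefault(call.intron_id, {})[cond] = call.retained
            novel[call.intron_id] = call.novel
    presence = (
        pd.DataFrame.from_dict(rows, orient="index")
        .reindex(columns=conditions)
        .fillna(False)
        .astype(bool)
        .sort_index()
    )
    presence = presence[presence.any(axis=1)]
    presence["novel"] = [novel[i] for i in presence.index]
    regions = (
        presence[conditions]
        .apply(lambda r: tuple(c for c in conditions if r[c]), axis=1)
        .value_counts()
        .sort_index()
    ) if len(presence) else pd.Series(dtype=int)
    return presence, regions


def pir_frame(estimates: Iterable[PirEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "intron_id": e.intron_id,
                "PIR5": e.PIR5,
                "PIR3": e.PIR3,
                "minPIR": e.minPIR,
                "coverage": e.coverage,
                "defined": e.defined,
            }
            for e in estimates
        ]
    )
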