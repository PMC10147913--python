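"""Amino-acid cross-feeding (metabolic cooperation) network inference.

Two genotypic groups X and Y cooperate over an amino acid ``a`` when the
conditioned-medium chemistry and the transcriptome agree on a directed
producer -> consumer relation.  Three evidence gates must all hold for an
edge X --a--> Y:

1. *Production*: X cultured in Y-conditioned medium shows relative
   amino-acid production > 1 for ``a`` (final-day over Day-0 mean
   concentration, Welch t-test p < alpha).
2. *Transcription*: the terminal gene of X's biosynthesis pathway for
   ``a`` is upregulated in coculture with Y (log2FC > 1, adjusted
   p < alpha).
3. *Utilisation*: Y cultured in X-conditioned medium shows relative
   production < 1 for ``a`` (same test).

The conjunction makes the inferred network a subset of the production-only
network; amino acids that are produced but lack transcriptional support,
or produced but not consumed by the partner, drop out without any
special-casing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .stats import two_sample_t

__all__ = [
    "AMINO_ACIDS",
    "ProductionCall",
    "CooperationEdge",
    "relative_production",
    "production_calls",
    "transcription_support",
    "infer_cooperation",
    "infer_network",
    "assemble_network",
]

#: The 18 free amino acids detected in the fermentation chemistry (HPLC);
#: asparagine and valine were not among them.
AMINO_ACIDS: tuple[str, ...] = (
    "alanine", "arginine", "aspartate", "cysteine", "glutamate", "glutamine",
    "glycine", "histidine", "isoleucine", "leucine", "lysine", "methionine",
    "phenylalanine", "proline", "serine", "threonine", "tryptophan", "tyrosine",
)


def _check_amino_acid(name: str) -> str:
    if name not in AMINO_ACIDS:
        raise ValueError(f"unknown amino acid {name!r}; expected one of the 18 detected")
    return name


@dataclass(frozen=True)
class ProductionCall:
    """Relative amino-acid production of one group in one conditioned medium.

    ``ratio`` is mean final-day concentration over mean Day-0 concentration;
    ``call`` is 'produced' (ratio > 1, p < alpha), 'utilised' (ratio < 1,
    p < alpha) or 'neutral'.
    """

    focal_group: str
    medium_source: str
    amino_acid: str
    ratio: float
    p: float
    call: str

    def __post_init__(self) -> None:
        _check_amino_acid(self.amino_acid)
        if self.call not in ("produced", "utilised", "neutral"):
            raise ValueError(f"invalid call {self.call!r}")


@dataclass(frozen=True)
class CooperationEdge:
    """Directed producer -> consumer relation for one amino acid."""

    producer: str
    consumer: str
    amino_acid: str
    producer_ratio: float
    producer_p: float
    consumer_ratio: float
    consumer_p: float
    terminal_log2fc: float
    terminal_p_adjusted: float

    def key(self) -> tuple[str, str, str]:
        return (self.producer, self.consumer, self.amino_acid)


def _classify(ratio: float, p: float, alpha: float) -> str:
    if p < alpha and ratio > 1:
        return "produced"
    if p < alpha and ratio < 1:
        return "utilised"
    return "neutral"


def relative_production(
    profile: pd.DataFrame,
    focal_group: str,
    medium_source: str,
    amino_acid: str,
    final_day: int = 8,
    alpha: float = 0.05,
    test: str = "concentrations",
) -> ProductionCall:
    """Relative amino-acid production for one (group, medium, amino acid).

    ``profile`` is the long conditioned-medium table with columns
    ``focal_group, medium_source, amino_acid, day, replicate,
    concentration``.  The ratio is mean(final day)/mean(Day 0); the
    two-sided Welch t-test compares final-day against Day-0 replicate
    concentrations (``test='concentrations'``, default) or per-replicate
    ratios against 1 (``test='ratios'``); direction is then read from the
    ratio.
    """
    _check_amino_acid(amino_acid)
    sel = profile[
        (profile["focal_group"] == focal_group)
        & (profile["medium_source"] == medium_source)
        & (profile["amino_acid"] == amino_acid)
    ]
    initial = sel.loc[sel["day"] == 0, "concentration"].to_numpy(dtype=float)
    final = sel.loc[sel["day"] == final_day, "concentration"].to_numpy(dtype=float)
    if initial.size < 2 or final.size < 2:
        raise ValueError(
            f"need >=2 replicates at Day 0 and Day {final_day} for "
            f"({focal_group}, {medium_source}, {amino_acid})"
        )
    c0 = float(initial.mean())
    if c0 == 0.0:
        raise ValueError("Day-0 mean concentration is zero; ratio undefined")
    ratio = float(final.mean()) / c0
    if test == "concentrations":
        _, p = two_sample_t(final, initial)
    elif test == "ratios":
        from scipy import stats as sps

        r = final / c0
        if np.ptp(r) == 0.0:
            p = 1.0 if r[0] == 1.0 else 0.0
        else:
            p = float(sps.ttest_1samp(r, 1.0).pvalue)
    else:
        raise ValueError(f"unknown test mode {test!r}")
    return ProductionCall(
        focal_group=focal_group,
        medium_source=medium_source,
        amino_acid=amino_acid,
        ratio=ratio,
        p=float(p),
        call=_classify(ratio, p, alpha),
    )


def production_calls(
    profile: pd.DataFrame,
    final_day: int = 8,
    alpha: float = 0.05,
    test: str = "concentrations",
) -> list[ProductionCall]:
    """All production calls present in a conditioned-medium profile table."""
    keys = profile[["focal_group", "medium_source", "amino_acid"]].drop_duplicates()
    return [
        relative_production(
            profile, row.focal_group, row.medium_source, row.amino_acid,
            final_day=final_day, alpha=alpha, test=test,
        )
        for row in keys.itertuples()
    ]


def transcription_support(
    records: pd.DataFrame,
    pathway: Mapping[tuple[str, str], str],
    focal_isolates: Sequence[str],
    condition: str,
    amino_acid: str,
    alpha: float = 0.05,
    log2fc_cutoff: float = 1.0,
    aggregation: str = "all",
) -> tuple[bool, pd.DataFrame]:
    """Is the terminal biosynthesis gene upregulated in coculture?

    For each focal isolate representing the candidate producer group, the
    terminal gene of the amino acid's biosynthesis pathway (from the
    pathway map) must show log2FC > cutoff with adjusted p < alpha in the
    given coculture condition.  ``aggregation='all'`` (default) requires
    every representative isolate to pass — the strict reading when a group
    is represented in more than one experiment set; ``'any'`` accepts one.

    Returns the boolean verdict plus the per-isolate evidence rows.
    """
    _check_amino_acid(amino_acid)
    if aggregation not in ("all", "any"):
        raise ValueError("aggregation must be 'all' or 'any'")
    verdicts = []
    evidence_rows = []
    for iso in focal_isolates:
        key = (iso, amino_acid)
        if key not in pathway:
            raise KeyError(f"no terminal gene mapped for isolate {iso!r}, {amino_acid}")
        gene = pathway[key]
        rec = records[
            (records["isolate"] == iso)
            & (records["gene"] == gene)
            & (records["condition"] == condition)
        ]
        if rec.empty:
            raise KeyError(
                f"no transcription record for gene {gene!r} of {iso!r} in condition {condition!r}"
            )
        fc = float(rec["log2_fold_change"].iloc[0])
        padj = float(rec["p_adjusted"].iloc[0])
        ok = fc > log2fc_cutoff and padj < alpha
        verdicts.append(ok)
        evidence_rows.append(
            {"isolate": iso, "gene": gene, "condition": condition,
             "amino_acid": amino_acid, "log2_fold_change": fc,
             "p_adjusted": padj, "supported": ok}
        )
    verdict = all(verdicts) if aggregation == "all" else any(verdicts)
    return verdict, pd.DataFrame(evidence_rows)


def infer_cooperation(
    calls: Iterable[ProductionCall],
    support: Mapping[str, tuple[float, float]] | Mapping[str, bool],
    pair: tuple[str, str],
    alpha: float = 0.05,
    log2fc_cutoff: float = 1.0,
) -> list[CooperationEdge]:
    """Cooperation edges X -> Y for one ordered pair of groups.

    ``calls`` must contain, for every amino acid considered, the call of X
    in Y-conditioned medium and the call of Y in X-conditioned medium.
    ``support`` maps amino acid -> terminal-gene evidence for the producer
    X in coculture with Y, either as a (log2FC, adjusted p) tuple or as an
    already-resolved boolean.  An edge is emitted iff X produced, the
    terminal gene is upregulated, and Y utilised.
    """
    x, y = pair
    x_in_y: dict[str, ProductionCall] = {}
    y_in_x: dict[str, ProductionCall] = {}
    for c in calls:
        if c.focal_group == x and c.medium_source == y:
            x_in_y[c.amino_acid] = c
        elif c.focal_group == y and c.medium_source == x:
            y_in_x[c.amino_acid] = c

    edges: list[CooperationEdge] = []
    for aa, prod in sorted(x_in_y.items()):
        if aa not in y_in_x:
            raise ValueError(
                f"missing reciprocal call for {aa}: have {x} in {y}-medium but not {y} in {x}-medium"
            )
        if prod.call != "produced":
            continue
        cons = y_in_x[aa]
        if cons.call != "utilised":
            continue
        ev = support.get(aa)
        if ev is None:
            continue
        if isinstance(ev, bool):
            ok, fc, padj = ev, np.nan, np.nan
        else:
            fc, padj = float(ev[0]), float(ev[1])
            ok = fc > log2fc_cutoff and padj < alpha
        if not ok:
            continue
        edges.append(
            CooperationEdge(
                producer=x, consumer=y, amino_acid=aa,
                producer_ratio=prod.ratio, producer_p=prod.p,
                consumer_ratio=cons.ratio, consumer_p=cons.p,
                terminal_log2fc=fc, terminal_p_adjusted=padj,
            )
        )
    edges.sort(key=lambda e: e.key())
    return edges


def infer_network(
    profile: pd.DataFrame,
    transcription: pd.DataFrame,
    pathway: Mapping[tuple[str, str], str],
    group_isolates: Mapping[str, Sequence[str]],
    final_day: int = 8,
    alpha: float = 0.05,
    log2fc_cutoff: float = 1.0,
    aggregation: str = "all",
    test: str = "concentrations",
) -> list[CooperationEdge]:
    """Full pipeline: production calls + transcription gates -> edge list.

    ``group_isolates`` maps each group label to the isolates representing
    it in the coculture transcription experiments.  Coculture conditions in
    the transcription table are expected to be labelled ``vs_<partner
    group>``.
    """
    calls = production_calls(profile, final_day=final_day, alpha=alpha, test=test)
    by_cond: dict[tuple[str, str], list[ProductionCall]] = {}
    for c in calls:
        by_cond.setdefault((c.focal_group, c.medium_source), []).append(c)

    edges: list[CooperationEdge] = []
    groups = sorted(group_isolates)
    for x in groups:
        for y in groups:
            if x == y or (x, y) not in by_cond:
                continue
            support: dict[str, tuple[float, float]] = {}
            for c in by_cond[(x, y)]:
                if c.call != "produced":
                    continue
                ok, ev = transcription_support(
                    transcription, pathway, group_isolates[x], f"vs_{y}",
                    c.amino_acid, alpha=alpha, log2fc_cutoff=log2fc_cutoff,
                    aggregation=aggregation,
                )
                # worst representative carries the reported evidence
                worst = ev.sort_values("log2_fold_change").iloc[0]
                support[c.amino_acid] = (
                    (float(worst["log2_fold_change"]), float(worst["p_adjusted"]))
                    if ok
                    else (-np.inf, 1.0)
                )
            pair_calls = by_cond[(x, y)] + by_cond.get((y, x), [])
            edges.extend(
                infer_cooperation(pair_calls, support, (x, y), alpha=alpha,
                                  log2fc_cutoff=log2fc_cutoff)
            )
    edges.sort(key=lambda e: e.key())
    return edges


def assemble_network(edges: Sequence[CooperationEdge]) -> tuple[nx.MultiDiGraph, dict]:
    """Directed multigraph of cooperation edges plus a JSON-ready summary.

    Edges are keyed by (producer, consumer, amino acid); duplicates are
    rejected.  The summary reports per-pair amino-acid sets, the number of
    distinct amino acids across all edges, and per-group in/out degrees.
    """
    g = nx.MultiDiGraph()
    seen: set[tuple[str, str, str]] = set()
    for e in edges:
        if e.key() in seen:
            raise ValueError(f"duplicate cooperation edge {e.key()}")
        seen.add(e.key())
        g.add_edge(
            e.producer, e.consumer, key=e.amino_acid,
            amino_acid=e.amino_acid,
            producer_ratio=e.producer_ratio, consumer_ratio=e.consumer_ratio,
            terminal_log2fc=e.terminal_log2fc,
        )
    per_pair: dict[str, list[str]] = {}
    for e in edges:
        per_pair.setdefault(f"{e.producer}->{e.consumer}", []).append(e.amino_acid)
    for v in per_pair.values():
        v.sort()
    amino_acids = sorted({e.amino_acid for e in edges})
    summary = {
        "n_edges": len(edges),
        "n_amino_acids": len(amino_acids),
        "amino_acids": amino_acids,
        "per_pair": per_pair,
        "out_degree": {n: g.out_degree(n) for n in sorted(g.nodes)},
        "in_degree": {n: g.in_degree(n) for n in sorted(g.nodes)},
    }
    return g, summary
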