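"""Drug query strategies: single method, consensus (rank aggregation),
and cross-signature quadrant analysis.

*Single method* scores one tagged signature with one method and extracts
the strongest mimics and reversers. *Consensus* integrates the rankings of
several methods per direction with robust rank aggregation (RRA), giving
each drug an overall score of -log10(aggregated P). *Cross-signature*
scores two signatures with a shared method and classifies drugs into sign
quadrants; drugs negative under both signatures are the promising
repurposing candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .errors import ValidationError
from .scoring import ScoreTable, score_panel
from .signature import ReferencePanel, TaggedSignature

__all__ = [
    "QueryResult",
    "AggregationResult",
    "QuadrantResult",
    "query_single",
    "rra_pvalue",
    "ss_all",
    "ss_cross",
]

THERAPEUTIC = "therapeutic"
AGONISTIC = "agonistic"


@dataclass(frozen=True)
class QueryResult:
    """Full score table plus the strongest drugs on each side."""

    table: ScoreTable
    top_positive: pd.Series  # mimics, score descending
    top_negative: pd.Series  # reversers, score ascending


def query_single(
    ts: TaggedSignature,
    panel: ReferencePanel,
    method: str,
    *,
    extreme_n: int | None = None,
    weight_p: float = 1.0,
    top_k: int = 5,
) -> QueryResult:
    """Classic one-signature, one-method query.

    Returns the complete score table together with the ``top_k`` highest
    positive (agonistic) and ``top_k`` most negative (therapeutic) drugs;
    a side is shorter when fewer drugs carry that sign."""
    st = score_panel(ts, panel, method, extreme_n=extreme_n, weight_p=weight_p)
    s = st.scores
    pos = s[s > 0].sort_values(ascending=False, kind="stable").head(top_k)
    neg = s[s < 0].sort_values(ascending=True, kind="stable").head(top_k)
    return QueryResult(table=st, top_positive=pos, top_negative=neg)


def rra_pvalue(normalized_ranks: Sequence[float], k: int | None = None) -> float:
    """Robust-rank-aggregation P-value for one item.

    Given the item's normalized ranks r_(1) <= ... <= r_(K) across K
    rankers, beta_k is the probability that the k-th smallest of K
    independent uniforms is <= r_(k) (a binomial tail); the score is
    rho = min_k beta_k, Bonferroni-corrected over k: p = min(1, rho * K).
    """
    r = np.sort(np.asarray(normalized_ranks, dtype=float))
    if k is None:
        k = len(r)
    if len(r) != k or k < 1:
        raise ValidationError("rra_pvalue needs exactly K normalized ranks, K >= 1")
    if np.any(r <= 0) or np.any(r > 1):
        raise ValidationError("normalized ranks must lie in (0, 1]")
    ks = np.arange(1, k + 1)
    betas = binom.sf(ks - 1, k, r)  # P(Bin(K, r_k) >= k)
    rho = float(betas.min())
    return min(1.0, rho * k)


@dataclass(frozen=True)
class AggregationResult:
    """Consensus result for one direction.

    ``table`` has one row per drug retrieved in the direction by at least
    one method (or by all, in strict mode): aggregated_p, overall_score
    (-log10 p), and support (number of methods agreeing on the direction),
    sorted by overall_score descending.
    """

    direction: str
    table: pd.DataFrame
    top: pd.DataFrame


def _direction_ranks(st: ScoreTable, direction: str, m: int) -> dict[str, float]:
    """Normalized rank rank/M of each drug carrying the direction's sign,
    ranked from strongest (most negative / most positive) to weakest."""
    s = st.scores
    if direction == THERAPEUTIC:
        side = s[s < 0]
        order = sorted(side.index, key=lambda d: (side[d], d))
    else:
        side = s[s > 0]
        order = sorted(side.index, key=lambda d: (-side[d], d))
    return {d: (i + 1) / m for i, d in enumerate(order)}


def ss_all(
    ts: TaggedSignature,
    panel: ReferencePanel,
    methods: Sequence[str],
    *,
    extreme_n: int | None = None,
    weight_p: float = 1.0,
    require_all: bool = False,
    top_k: int = 10,
    score_tables: Sequence[ScoreTable] | None = None,
) -> dict[str, AggregationResult]:
    """Consensus query across several methods, per direction.

    For each direction a drug's normalized rank under each method is its
    rank among same-direction drugs divided by the panel size M; a method
    that does not place the drug in the direction contributes the worst
    rank 1 (the convention for unobserved items). Ranks are aggregated with
    ``rra_pvalue`` over K = len(methods) and each drug scored
    -log10(aggregated P). With ``require_all`` only drugs on which every
    method agrees in direction are kept.
    """
    if len(methods) < 2:
        raise ValidationError("consensus needs at least 2 methods")
    if score_tables is None:
        score_tables = [
            score_panel(ts, panel, mth, extreme_n=extreme_n, weight_p=weight_p)
            for mth in methods
        ]
    m = panel.n_drugs
    k = len(methods)
    out: dict[str, AggregationResult] = {}
    for direction in (THERAPEUTIC, AGONISTIC):
        per_method = [_direction_ranks(st, direction, m) for st in score_tables]
        drugs = sorted(set().union(*[set(r) for r in per_method]))
        if require_all:
            drugs = [d for d in drugs if all(d in r for r in per_method)]
        rows = []
        for d in drugs:
            ranks = [r.get(d, 1.0) for r in per_method]
            p = rra_pvalue(ranks, k)
            rows.append(
                {
                    "drug": d,
                    "aggregated_p": p,
                    "overall_score": -np.log10(p),
                    "support": sum(d in r for r in per_method),
                }
            )
        table = pd.DataFrame(
            rows, columns=["drug", "aggregated_p", "overall_score", "support"]
        )
        if len(table):
            table = table.sort_values(
                ["overall_score", "drug"], ascending=[False, True], kind="stable"
            ).reset_index(drop=True)
        else:
            import warnings

            warnings.warn(f"no drug retrieved in the {direction} direction", stacklevel=2)
        out[direction] = AggregationResult(
            direction=direction, table=table, top=table.head(top_k)
        )
    return out


@dataclass(frozen=True)
class QuadrantResult:
    """Per-drug scores under two signatures with quadrant classification.

    ``table`` columns: drug, score_sig1, score_sig2, quadrant in
    {'++', '+-', '-+', '--'} by sign pair; a drug with a zero score sits on
    an axis and gets no quadrant (empty string). ``promising`` lists the
    '--' drugs by combined score ascending (most reversing first).
    """

    table: pd.DataFrame
    promising: pd.DataFrame


def _quadrant(s1: float, s2: float) -> str:
    if s1 == 0 or s2 == 0:
        return ""
    return ("+" if s1 > 0 else "-") + ("+" if s2 > 0 else "-")


def ss_cross(
    ts1: TaggedSignature,
    ts2: TaggedSignature,
    panel: ReferencePanel,
    method: str,
    *,
    extreme_n: int | None = None,
    weight_p: float = 1.0,
) -> QuadrantResult:
    """Cross-signature query: score two signatures with one shared method
    and classify every drug by the signs of its two scores."""
    st1 = score_panel(ts1, panel, method, extreme_n=extreme_n, weight_p=weight_p)
    st2 = score_panel(ts2, panel, method, extreme_n=extreme_n, weight_p=weight_p)
    table = pd.DataFrame(
        {
            "drug": list(st1.scores.index),
            "score_sig1": st1.scores.to_numpy(),
            "score_sig2": st2.scores.reindex(st1.scores.index).to_numpy(),
        }
    )
    table["quadrant"] = [
        _quadrant(a, b) for a, b in zip(table["score_sig1"], table["score_sig2"])
    ]
    promising = (
        table[table["quadrant"] == "--"]
        .assign(combined=lambda df: df["score_sig1"] + df["score_sig2"])
        .sort_values(["combined", "drug"], kind="stable")
        .reset_index(drop=True)
    )
    return QuadrantResult(table=table, promising=promising)
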