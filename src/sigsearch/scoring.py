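"""The five signature search methods (SSMs).

Each method scores a tagged disease signature against one drug column of a
reference panel. The sign convention throughout is: **negative = reversal**
(the drug shifts signature genes opposite to the disease direction, i.e. a
potential therapeutic), **positive = mimic** (agonistic).

Methods
-------
XSum
    Sum of the drug's perturbation statistics over up-tags minus down-tags,
    restricted to the drug's own extreme (top/bottom ``extreme_n``) genes.
    Unbounded.
CMap
    Difference of Kolmogorov-Smirnov running statistics for the up- and
    down-tag sets, zeroed when both deviate the same way, then scaled
    per panel to [-1, 1].
GSEA
    Two-sided connectivity built from the weighted running-sum enrichment
    score: (ES_up - ES_down)/2 when the two enrichment scores have opposite
    signs, else 0. In [-1, 1].
ZhangScore
    Signed-rank connection score: the inner product of signature and
    reference signed magnitude-ranks over the tag genes, normalized by the
    maximum achievable magnitude. In [-1, 1].
XCos
    Cosine similarity between signature stats and drug stats on the tag
    genes that fall in the drug's extremes. In [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ScoringError, ValidationError
from .signature import ReferencePanel, TaggedSignature, validate_against_panel

__all__ = [
    "METHODS",
    "RankedProfile",
    "ScoreTable",
    "rank_profile",
    "ks_statistic",
    "score_cmap",
    "scale_scores",
    "score_gsea",
    "score_zhang",
    "extreme_set",
    "score_xsum",
    "score_xcos",
    "score_panel",
    "default_extreme_n",
]

#: The supported signature search methods, in canonical order.
METHODS: tuple[str, ...] = ("XSum", "CMap", "GSEA", "ZhangScore", "XCos")


@dataclass(frozen=True)
class RankedProfile:
    """One drug column prepared for rank-based scoring.

    ``gene_order`` lists the panel's genes sorted by the drug's statistic,
    descending (ties broken by gene id). ``position`` maps gene -> 1-based
    position in that order. ``signed_rank`` maps gene -> rank of |stat|
    (1 = smallest magnitude) carrying the sign of the stat.
    """

    drug_id: str
    gene_order: tuple[str, ...]
    stats: Mapping[str, float]
    position: Mapping[str, int]
    signed_rank: Mapping[str, float]

    @property
    def n_genes(self) -> int:
        return len(self.gene_order)


def rank_profile(panel: ReferencePanel, drug_id: str) -> RankedProfile:
    """Build (and cache on the panel) the ranked profile for one drug."""
    cached = panel._profile_cache.get(drug_id)
    if cached is not None:
        return cached
    col = panel.column(drug_id)  # raises for unknown drug
    genes = np.asarray([str(g) for g in col.index], dtype=object)
    stats = col.to_numpy(dtype=float)

    desc = np.lexsort((genes, -stats))
    gene_order = tuple(genes[desc])
    position = {g: i + 1 for i, g in enumerate(gene_order)}

    mag = np.lexsort((genes, np.abs(stats)))
    signed_rank: dict[str, float] = {}
    for r, idx in enumerate(mag, start=1):
        signed_rank[str(genes[idx])] = float(np.sign(stats[idx]) * r)

    prof = RankedProfile(
        drug_id=drug_id,
        gene_order=gene_order,
        stats={str(g): float(s) for g, s in zip(genes, stats)},
        position=position,
        signed_rank=signed_rank,
    )
    panel._profile_cache[drug_id] = prof
    return prof


def ks_statistic(tag_positions: Sequence[int], n_genes: int) -> float:
    """Kolmogorov-Smirnov running statistic of a tag set within a ranked list.

    With sorted tag positions V(1..t) in a list of n genes:

        a = max_j ( j/t - V(j)/n )
        b = max_j ( V(j)/n - (j-1)/t )

    Returns ``a`` if ``a > b`` else ``-b``. Positive means the tags
    concentrate near the top of the list, negative near the bottom.
    """
    pos = np.asarray(sorted(tag_positions), dtype=float)
    t = len(pos)
    if t == 0:
        raise ScoringError("ks_statistic requires at least one tag position")
    if pos[0] < 1 or pos[-1] > n_genes:
        raise ScoringError("tag positions must lie in 1..n_genes")
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - pos / n_genes))
    b = float(np.max(pos / n_genes - (j - 1) / t))
    return a if a > b else -b


def _present_positions(tags: Iterable[str], rp: RankedProfile) -> list[int]:
    return sorted(rp.position[g] for g in tags if g in rp.position)


def score_cmap(ts: TaggedSignature, rp: RankedProfile) -> float:
    """Raw (unscaled) connectivity score: ks_up - ks_down, zeroed when the
    two KS statistics deviate in the same direction."""
    up = _present_positions(ts.up_tags, rp)
    down = _present_positions(ts.down_tags, rp)
    if not up:
        raise ScoringError(f"no up tags present in profile {rp.drug_id!r}")
    if not down:
        raise ScoringError(f"no down tags present in profile {rp.drug_id!r}")
    ks_up = ks_statistic(up, rp.n_genes)
    ks_down = ks_statistic(down, rp.n_genes)
    if ks_up * ks_down < 0:
        return ks_up - ks_down
    return 0.0


def scale_scores(raw: Mapping[str, float] | pd.Series) -> pd.Series:
    """Panel-wide scaling to [-1, 1]: positives divided by the maximum
    positive, negatives by the magnitude of the minimum negative, zeros kept."""
    s = pd.Series(raw, dtype=float)
    if len(s) == 0:
        raise ValidationError("scale_scores requires at least one drug")
    out = s.copy()
    pos = s[s > 0]
    if len(pos):
        out[s > 0] = s[s > 0] / pos.max()
    neg = s[s < 0]
    if len(neg):
        out[s < 0] = s[s < 0] / abs(neg.min())
    return out


def _running_es(positions: Sequence[int], weights: np.ndarray, n: int) -> float:
    """Signed maximum deviation of the weighted enrichment running sum.

    Hits at sorted ``positions`` increment by weight/sum(weights); each miss
    decrements by 1/(n - t). Returns the running-sum value of largest
    magnitude over the whole walk (positive branch wins ties).
    """
    pos = np.asarray(positions, dtype=float)
    t = len(pos)
    if t == 0:
        raise ScoringError("enrichment running sum requires at least one hit")
    if t >= n:
        raise ScoringError("tag set must be a strict subset of the ranked list")
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:  # all-zero weights (e.g. flat stats under p>0): fall back to unweighted
        w = np.ones_like(w)
        total = float(t)
    miss = 1.0 / (n - t)
    cum = np.cumsum(w) / total
    j = np.arange(1, t + 1, dtype=float)
    after = cum - (pos - j) * miss          # running sum just after each hit
    before = (cum - w / total) - (pos - j) * miss  # just before each hit
    peak = max(float(after.max()), 0.0)
    trough = min(float(before.min()), 0.0)
    # exact peak/-trough ties (common for unweighted sums at symmetric
    # positions) go to the positive branch, robust to float rounding
    return peak if peak >= -trough - 1e-12 else trough


def score_gsea(ts: TaggedSignature, rp: RankedProfile, weight_p: float = 1.0) -> float:
    """Two-sided weighted-enrichment connectivity in [-1, 1].

    ES_up and ES_down are maximum-deviation running sums over the drug's
    ranked gene list, hits weighted by |stat|^p normalized over tag hits.
    Connectivity is (ES_up - ES_down)/2 when they disagree in sign, else 0.
    """
    if weight_p < 0:
        raise ValidationError("weight_p must be >= 0")

    def _side(tags: tuple[str, ...], side: str) -> float:
        pos = _present_positions(tags, rp)
        if not pos:
            raise ScoringError(f"no {side} tags present in profile {rp.drug_id!r}")
        order = rp.gene_order
        w = np.array(
            [abs(rp.stats[order[p - 1]]) ** weight_p for p in pos], dtype=float
        )
        return _running_es(pos, w, rp.n_genes)

    es_up = _side(ts.up_tags, "up")
    es_down = _side(ts.down_tags, "down")
    if es_up * es_down < 0:
        return (es_up - es_down) / 2.0
    return 0.0


def score_zhang(ts: TaggedSignature, rp: RankedProfile) -> float:
    """Signed-rank connection score in [-1, 1].

    Signature tags get signed ranks by |signature stat| among the tags
    present in the panel (1 = smallest, sign = direction); the drug's stats
    on those same genes are re-ranked among themselves the same way. The
    score is the inner product divided by the maximum achievable magnitude
    (largest ranks paired together). Tags absent from the panel contribute
    nothing and shrink the denominator.
    """
    sig_stats = ts.stat_map
    if not sig_stats:
        raise ValidationError("ZhangScore needs signature stats on the tag sets")
    genes = [g for g in ts.all_tags if g in rp.position]
    if not genes:
        raise ScoringError(f"no tags present in profile {rp.drug_id!r}")
    t = len(genes)
    sig_sign = {g: (1.0 if g in ts.up_tags else -1.0) for g in genes}

    def _signed_ranks(values: Mapping[str, float], signs: Mapping[str, float]) -> dict[str, float]:
        order = sorted(genes, key=lambda g: (abs(values[g]), g))
        return {g: signs[g] * (i + 1) for i, g in enumerate(order)}

    s = _signed_ranks(sig_stats, sig_sign)
    ref_sign = {g: float(np.sign(rp.stats[g])) for g in genes}
    r = _signed_ranks(rp.stats, ref_sign)
    raw = sum(s[g] * r[g] for g in genes)
    max_sum = sum((k + 1) ** 2 for k in range(t))
    return raw / max_sum


def default_extreme_n(n_genes: int) -> int:
    """Customary eXtreme restriction: 500 genes per tail on full-size panels,
    otherwise half the gene universe."""
    return 500 if n_genes >= 1000 else n_genes // 2


def extreme_set(rp: RankedProfile, extreme_n: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """The drug's top and bottom ``extreme_n`` genes by statistic."""
    if extreme_n < 1:
        raise ValidationError("extreme_n must be a positive integer")
    if 2 * extreme_n > rp.n_genes:
        raise ValidationError(
            f"extreme_n={extreme_n} too large for {rp.n_genes} genes"
        )
    return rp.gene_order[:extreme_n], rp.gene_order[-extreme_n:]


def score_xsum(ts: TaggedSignature, rp: RankedProfile, extreme_n: int) -> float:
    """eXtreme sum: sum of drug stats over up-tags minus down-tags, counting
    only tags inside the drug's extreme gene sets. Unbounded."""
    top, bottom = extreme_set(rp, extreme_n)
    ext = set(top) | set(bottom)
    up = sum(rp.stats[g] for g in ts.up_tags if g in ext)
    down = sum(rp.stats[g] for g in ts.down_tags if g in ext)
    return float(up - down)


def score_xcos(ts: TaggedSignature, rp: RankedProfile, extreme_n: int) -> float:
    """eXtreme cosine: cosine similarity between signature stats and drug
    stats over the tag genes inside the drug's extremes; 0 when no tag is
    extreme or a vector has zero norm."""
    sig_stats = ts.stat_map
    if not sig_stats:
        raise ValidationError("XCos needs signature stats on the tag sets")
    top, bottom = extreme_set(rp, extreme_n)
    ext = set(top) | set(bottom)
    shared = [g for g in ts.all_tags if g in ext and g in rp.stats]
    if not shared:
        warnings.warn(
            f"no signature tags inside the extremes of {rp.drug_id!r}; XCos = 0",
            stacklevel=2,
        )
        return 0.0
    x = np.array([sig_stats[g] for g in shared], dtype=float)
    y = np.array([rp.stats[g] for g in shared], dtype=float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


@dataclass(frozen=True)
class ScoreTable:
    """Scores of one (method, TopN) cell: one signed score per panel drug."""

    method: str
    topn: int
    scores: pd.Series  # index drug_id, float

    def to_frame(self) -> pd.DataFrame:
        """Tabular output: drug, method, topn, score, rank (1 = most
        negative, i.e. strongest predicted reversal)."""
        df = pd.DataFrame(
            {
                "drug": self.scores.index,
                "method": self.method,
                "topn": self.topn,
                "score": self.scores.to_numpy(),
            }
        )
        df["rank"] = df["score"].rank(method="first").astype(int)
        return df.sort_values("rank", kind="stable").reset_index(drop=True)


def score_panel(
    ts: TaggedSignature,
    panel: ReferencePanel,
    method: str,
    *,
    extreme_n: int | None = None,
    weight_p: float = 1.0,
) -> ScoreTable:
    """Score a tagged signature against every drug in the panel.

    CMap raw scores are panel-scaled to [-1, 1]; the other methods are
    returned as computed. Per-drug failures are re-raised with the drug id
    attached.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; expected one of {METHODS}")
    validate_against_panel(ts, panel)
    if extreme_n is None:
        extreme_n = default_extreme_n(panel.n_genes)

    scores: dict[str, float] = {}
    for drug in panel.drug_ids:
        rp = rank_profile(panel, drug)
        try:
            if method == "XSum":
                scores[drug] = score_xsum(ts, rp, extreme_n)
            elif method == "CMap":
                scores[drug] = score_cmap(ts, rp)
            elif method == "GSEA":
                scores[drug] = score_gsea(ts, rp, weight_p)
            elif method == "ZhangScore":
                scores[drug] = score_zhang(ts, rp)
            else:  # XCos
                scores[drug] = score_xcos(ts, rp, extreme_n)
        except ScoringError as exc:
            raise ScoringError(f"{method} failed for drug {drug!r}: {exc}") from exc

    series = pd.Series(scores, dtype=float).reindex(panel.drug_ids)
    if method == "CMap":
        series = scale_scores(series)
    return ScoreTable(method=method, topn=ts.topn, scores=series)
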