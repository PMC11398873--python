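"""Annotation-free method evaluation via drug self-retrieval.

When no trustworthy drug annotation exists for a disease (rare cancers,
cancer subtypes), each drug's own perturbation profile can serve as a
query: the drug's top/bottom TopN genes are treated as an up/down tag
signature and scored against every drug in the panel. A good method
retrieves the originating drug at the top of the mimic (positive) end.
Per-drug retrieval ranks are summarized by a performance score in [0, 1]
(1 = every drug self-retrieves first; 0.5 expected under random ranking).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .scoring import score_panel
from .signature import (
    GeneSignature,
    ReferencePanel,
    TaggedSignature,
    build_topn_signature,
)

__all__ = ["SelfRetrievalResult", "build_drug_query", "self_retrieval", "performance_score"]


@dataclass(frozen=True)
class SelfRetrievalResult:
    """Self-retrieval ranks and their performance-score summary."""

    method: str
    topn: int
    ranks: pd.Series  # drug_id -> rank of the drug's own column (1 = best)
    performance_score: float


def build_drug_query(panel: ReferencePanel, drug_id: str, topn: int) -> TaggedSignature:
    """Tailor a drug's own column into a TopN up/down tag signature."""
    col = panel.column(drug_id)
    sig = GeneSignature(
        genes=tuple(str(g) for g in col.index),
        stats=tuple(float(v) for v in col.to_numpy()),
    )
    return build_topn_signature(sig, topn)


def performance_score(ranks: pd.Series | dict, m: int) -> float:
    """Normalized mean retrieval rank: PS = mean((M - rank) / (M - 1)).

    1 when every drug is retrieved at rank 1, 0 when every drug comes last,
    expectation 0.5 under uniformly random ranking."""
    if m < 2:
        raise ValidationError("performance score needs at least 2 drugs")
    r = pd.Series(ranks, dtype=float)
    return float(((m - r) / (m - 1)).mean())


def self_retrieval(
    panel: ReferencePanel,
    method: str,
    topn: int,
    *,
    extreme_n: int | None = None,
    weight_p: float = 1.0,
    query_noise_sd: float = 0.0,
    seed: int | None = None,
) -> SelfRetrievalResult:
    """Query the panel with every drug's own signature and rank the drug
    in its result list.

    Scores are sorted descending (a self-match is a mimic, hence maximally
    positive); tied scores share the mean rank. ``query_noise_sd`` adds
    seeded Gaussian noise to each column *before* the query tags are
    derived — the panel itself stays clean — emulating replicate noise in
    the profile the query is built from.
    """
    if panel.n_drugs < 2:
        raise ValidationError("self-retrieval needs a panel with at least 2 drugs")
    rng = np.random.default_rng(seed)
    ranks: dict[str, float] = {}
    for drug in panel.drug_ids:
        if query_noise_sd > 0:
            col = panel.column(drug)
            noisy = col.to_numpy() + rng.normal(0.0, query_noise_sd, len(col))
            sig = GeneSignature(
                genes=tuple(str(g) for g in col.index),
                stats=tuple(float(v) for v in noisy),
            )
            query = build_topn_signature(sig, topn)
        else:
            query = build_drug_query(panel, drug, topn)
        st = score_panel(query, panel, method, extreme_n=extreme_n, weight_p=weight_p)
        # rank 1 = highest positive score; ties -> mean rank
        desc_ranks = rankdata(-st.scores.to_numpy(), method="average")
        ranks[drug] = float(desc_ranks[list(st.scores.index).index(drug)])
    series = pd.Series(ranks).reindex(panel.drug_ids)
    ps = performance_score(series, panel.n_drugs)
    return SelfRetrievalResult(method=method, topn=topn, ranks=series, performance_score=ps)
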