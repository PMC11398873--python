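"""Annotation-based benchmarking of method x TopN cells.

Two indices evaluate one score table against drug annotations:

AUC
    Area under the ROC curve with the *negated* score predicting the
    "Effective" label — therapeutic drugs are expected to score negative,
    so a perfectly reversing method attains AUC 1. Ties count 1/2.
ES
    Running-sum enrichment of the effective drug set within the score-sorted
    (descending) drug list. Effective drugs clustered at the negative end
    give ES near -1; a *lower* ES indicates a better method.

``benchmark_sweep`` evaluates every (method, TopN) combination and
``select_optimal`` picks the best cell per index (argmax AUC, argmin ES).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import ScoringError, ValidationError
from .scoring import METHODS, ScoreTable, _running_es, score_panel
from .signature import GeneSignature, ReferencePanel, build_topn_signature

__all__ = [
    "AnnotationSet",
    "BenchmarkGrid",
    "compute_auc",
    "compute_es",
    "benchmark_sweep",
    "select_optimal",
    "DEFAULT_TOPN_GRID",
]

#: Default TopN sweep, spanning customary oncogenic-signature sizes.
DEFAULT_TOPN_GRID: tuple[int, ...] = (50, 100, 150, 200, 250, 300, 350, 400, 450, 500)

EFFECTIVE = "Effective"
INEFFECTIVE = "Ineffective"


@dataclass(frozen=True)
class AnnotationSet:
    """Drug annotations in one of two modes.

    AUC mode carries an Effective/Ineffective label per annotated drug
    (suited to large experimental screens, e.g. IC50 classifications).
    ES mode carries only the set of drugs known to be effective (suited to
    sparse clinical indication lists).
    """

    mode: str  # "AUC" | "ES"
    labels: Mapping[str, str] | None = None
    effective_set: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.mode == "AUC":
            if not self.labels:
                raise ValidationError("AUC annotation needs drug labels")
            bad = {v for v in self.labels.values()} - {EFFECTIVE, INEFFECTIVE}
            if bad:
                raise ValidationError(f"labels must be Effective/Ineffective, got {bad}")
        elif self.mode == "ES":
            if not self.effective_set:
                raise ValidationError("ES annotation needs a non-empty effective set")
        else:
            raise ValidationError(f"unknown annotation mode {self.mode!r}")

    @classmethod
    def from_labels(cls, labels: Mapping[str, str]) -> "AnnotationSet":
        return cls(mode="AUC", labels=dict(labels))

    @classmethod
    def from_effective(cls, drugs: Iterable[str]) -> "AnnotationSet":
        return cls(mode="ES", effective_set=frozenset(drugs))


def compute_auc(st: ScoreTable, ann: AnnotationSet) -> float:
    """ROC AUC of -score predicting the Effective label, over annotated
    drugs present in the score table."""
    if ann.mode != "AUC":
        raise ValidationError("compute_auc needs an AUC-mode annotation")
    common = [d for d in st.scores.index if d in ann.labels]
    y = np.array([1 if ann.labels[d] == EFFECTIVE else 0 for d in common])
    if len(common) == 0 or y.sum() == 0 or y.sum() == len(y):
        raise ValidationError(
            "AUC needs at least one Effective and one Ineffective drug in the panel"
        )
    predictor = -st.scores.loc[common].to_numpy()
    return float(roc_auc_score(y, predictor))


def compute_es(st: ScoreTable, ann: AnnotationSet, weight_p: float = 0.0) -> float:
    """Enrichment of the effective set in the descending score ordering.

    Drugs are sorted by score descending (ties by drug id); the running sum
    gains 1/|hits| at each effective drug (|score|^p-weighted when p > 0)
    and loses 1/(M - |hits|) otherwise. Returns the signed maximum
    deviation: negative when effective drugs sit at the reversal end.
    """
    if ann.mode != "ES":
        raise ValidationError("compute_es needs an ES-mode annotation")
    drugs = list(st.scores.index)
    order = sorted(drugs, key=lambda d: (-st.scores[d], d))
    hits = [i + 1 for i, d in enumerate(order) if d in ann.effective_set]
    m = len(order)
    if len(hits) == 0 or len(hits) >= m:
        raise ValidationError(
            "ES needs 1 <= |effective drugs in panel| < number of panel drugs"
        )
    w = np.array([abs(st.scores[order[p - 1]]) ** weight_p for p in hits], dtype=float)
    return _running_es(hits, w, m)


@dataclass
class BenchmarkGrid:
    """Evaluation surface over (method, TopN) cells.

    ``cells`` maps (method, topn) -> {"auc": float} and/or {"es": float};
    cells that failed are recorded in ``failures`` with the reason.
    """

    cells: dict[tuple[str, int], dict[str, float]] = field(default_factory=dict)
    failures: dict[tuple[str, int], str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (method, topn), vals in sorted(self.cells.items()):
            for index, value in sorted(vals.items()):
                rows.append(
                    {"method": method, "topn": topn, "index": index, "value": value}
                )
        return pd.DataFrame(rows, columns=["method", "topn", "index", "value"])


def benchmark_sweep(
    sig: GeneSignature,
    panel: ReferencePanel,
    methods: Sequence[str] = METHODS,
    topn_grid: Sequence[int] = DEFAULT_TOPN_GRID,
    annotations: Sequence[AnnotationSet] = (),
    *,
    require_significant: bool = False,
    extreme_n: int | None = None,
    weight_p: float = 1.0,
    es_weight_p: float = 0.0,
) -> BenchmarkGrid:
    """Evaluate every (method, TopN) cell with every supplied annotation.

    Each cell tailors the signature to TopN tags, scores the full panel,
    and computes AUC and/or ES depending on annotation modes. Cells whose
    scoring fails are recorded as missing with the reason rather than
    aborting the sweep.
    """
    if not annotations:
        raise ValidationError("benchmark_sweep needs at least one annotation set")
    grid = BenchmarkGrid()
    for topn in topn_grid:
        try:
            ts = build_topn_signature(sig, topn, require_significant)
        except ValidationError as exc:
            for method in methods:
                grid.failures[(method, topn)] = str(exc)
            continue
        for method in methods:
            try:
                st = score_panel(
                    ts, panel, method, extreme_n=extreme_n, weight_p=weight_p
                )
                cell: dict[str, float] = {}
                for ann in annotations:
                    if ann.mode == "AUC":
                        cell["auc"] = compute_auc(st, ann)
                    else:
                        cell["es"] = compute_es(st, ann, es_weight_p)
                grid.cells[(method, topn)] = cell
            except (ScoringError, ValidationError) as exc:
                grid.failures[(method, topn)] = str(exc)
    if not grid.cells:
        raise ValidationError(
            f"no benchmark cell could be computed; first failure: "
            f"{next(iter(grid.failures.values()), 'none')}"
        )
    return grid


def select_optimal(grid: BenchmarkGrid) -> dict[str, tuple[str, int]]:
    """Best cell per index: highest AUC, lowest ES.

    Ties are broken by smaller TopN, then method name order."""
    if not grid.cells:
        raise ValidationError("benchmark grid has no complete cells")
    out: dict[str, tuple[str, int]] = {}
    for index, better in (("auc", max), ("es", min)):
        entries = [
            (vals[index], method, topn)
            for (method, topn), vals in grid.cells.items()
            if index in vals
        ]
        if not entries:
            continue
        best_val = better(e[0] for e in entries)
        candidates = [(topn, method) for val, method, topn in entries if val == best_val]
        topn, method = min(candidates)
        out[index] = (method, topn)
    return out
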