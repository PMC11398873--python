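"""Gene signatures, tag sets, and reference perturbation panels.

An *oncogenic signature* is a list of genes with signed differential
expression statistics (typically log fold changes), representing a disease
state. Querying a perturbation panel requires tailoring the signature to a
balanced pair of tag sets: the TopN most up-regulated and TopN most
down-regulated genes. The *reference panel* is a genes x drugs matrix of
perturbation statistics; each drug column is one "drug signature".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "GeneSignature",
    "TaggedSignature",
    "ReferencePanel",
    "CoverageReport",
    "build_topn_signature",
    "validate_against_panel",
]


@dataclass(frozen=True)
class GeneSignature:
    """A full differential-expression signature.

    Parameters
    ----------
    genes
        Gene identifiers, unique within the signature.
    stats
        Signed differential-expression statistic per gene (e.g. log2 fold
        change). Must contain at least one positive and one negative value,
        otherwise TopN filtration is undefined.
    significant
        Optional boolean flag per gene (e.g. adjusted p-value below a
        threshold computed upstream). When present, TopN filtration can be
        restricted to flagged genes.
    """

    genes: tuple[str, ...]
    stats: tuple[float, ...]
    significant: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.stats):
            raise ValidationError("genes and stats must have equal length")
        if self.significant is not None and len(self.significant) != len(self.genes):
            raise ValidationError("significant flag length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene ids must be unique within a signature")
        arr = np.asarray(self.stats, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("signature stats must be finite")
        if not ((arr > 0).any() and (arr < 0).any()):
            raise ValidationError(
                "signature needs at least one up- and one down-regulated gene"
            )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneSignature":
        """Build from a frame with columns ``gene``, ``stat`` [, ``significant``]."""
        if "gene" not in df.columns or "stat" not in df.columns:
            raise ValidationError("signature table needs 'gene' and 'stat' columns")
        sig = None
        if "significant" in df.columns:
            sig = tuple(bool(x) for x in df["significant"])
        return cls(
            genes=tuple(str(g) for g in df["gene"]),
            stats=tuple(float(s) for s in df["stat"]),
            significant=sig,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"gene": list(self.genes), "stat": list(self.stats)}
        if self.significant is not None:
            data["significant"] = list(self.significant)
        return pd.DataFrame(data)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class TaggedSignature:
    """Balanced up/down tag sets produced by TopN tailored filtration.

    ``up_stats``/``down_stats`` carry the originating signature statistic for
    each tag (needed by rank- and cosine-based scoring methods); they may be
    omitted when only set membership matters.
    """

    up_tags: tuple[str, ...]
    down_tags: tuple[str, ...]
    topn: int
    up_stats: tuple[float, ...] | None = None
    down_stats: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.topn < 1:
            raise ValidationError("topn must be a positive integer")
        if len(self.up_tags) != self.topn or len(self.down_tags) != self.topn:
            raise ValidationError(
                f"tag sets must both have size topn={self.topn} "
                f"(got {len(self.up_tags)} up, {len(self.down_tags)} down)"
            )
        if set(self.up_tags) & set(self.down_tags):
            raise ValidationError("up and down tags must be disjoint")
        for stats, tags, side in (
            (self.up_stats, self.up_tags, "up"),
            (self.down_stats, self.down_tags, "down"),
        ):
            if stats is not None and len(stats) != len(tags):
                raise ValidationError(f"{side}_stats length mismatch")

    @property
    def stat_map(self) -> Mapping[str, float]:
        """Tag gene -> signature stat; empty when stats were not supplied."""
        out: dict[str, float] = {}
        if self.up_stats is not None:
            out.update(zip(self.up_tags, self.up_stats))
        if self.down_stats is not None:
            out.update(zip(self.down_tags, self.down_stats))
        return out

    @property
    def all_tags(self) -> tuple[str, ...]:
        return self.up_tags + self.down_tags


@dataclass
class ReferencePanel:
    """Genes x drugs matrix of perturbation statistics.

    Wraps a float DataFrame (index = gene ids, columns = drug ids). Columns
    must be rankable: every drug needs at least two distinct values.
    """

    data: pd.DataFrame
    _profile_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in panel: {dupes[:5]}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate drug ids in panel: {dupes[:5]}")
        try:
            self.data = df = df.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"panel contains non-numeric values: {exc}") from exc
        if df.isna().any().any():
            raise ValidationError("panel contains missing values")
        nun = df.nunique(axis=0)
        flat = nun[nun < 2]
        if len(flat):
            raise ValidationError(
                f"panel columns are constant (not rankable): {flat.index.tolist()[:5]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def drug_ids(self) -> list[str]:
        return [str(d) for d in self.data.columns]

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.data.shape[1]

    def column(self, drug_id: str) -> pd.Series:
        if drug_id not in self.data.columns:
            raise ValidationError(f"drug {drug_id!r} not in panel")
        return self.data[drug_id]

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.data.columns


def build_topn_signature(
    sig: GeneSignature, topn: int, require_significant: bool = False
) -> TaggedSignature:
    """Tailor a full signature to balanced TopN up/down tag sets.

    Genes are ordered by the signed statistic within each direction: the
    ``topn`` largest positive stats become up-tags (descending) and the
    ``topn`` most negative become down-tags (ascending). Ties are broken by
    gene id so the result is deterministic and independent of input order.

    With ``require_significant=True`` only genes whose significance flag is
    set are eligible; the signature must then carry the flag.
    """
    if topn < 1:
        raise ValidationError("topn must be a positive integer")
    genes = np.asarray(sig.genes, dtype=object)
    stats = np.asarray(sig.stats, dtype=float)
    if require_significant:
        if sig.significant is None:
            raise ValidationError(
                "require_significant=True but signature has no significance flag"
            )
        keep = np.asarray(sig.significant, dtype=bool)
        genes, stats = genes[keep], stats[keep]

    def _select(mask: np.ndarray, descending: bool, side: str):
        g, s = genes[mask], stats[mask]
        if len(g) < topn:
            raise ValidationError(
                f"{side} direction has {len(g)} < {topn} eligible genes"
            )
        key = -s if descending else s
        order = np.lexsort((g, key))[:topn]
        return tuple(str(x) for x in g[order]), tuple(float(x) for x in s[order])

    up_tags, up_stats = _select(stats > 0, descending=True, side="up")
    down_tags, down_stats = _select(stats < 0, descending=False, side="down")
    return TaggedSignature(
        up_tags=up_tags,
        down_tags=down_tags,
        topn=topn,
        up_stats=up_stats,
        down_stats=down_stats,
    )


@dataclass(frozen=True)
class CoverageReport:
    """How many signature tags are present in a panel's gene universe."""

    present_up: int
    present_down: int
    absent_up: tuple[str, ...]
    absent_down: tuple[str, ...]

    @property
    def present(self) -> int:
        return self.present_up + self.present_down

    @property
    def absent(self) -> int:
        return len(self.absent_up) + len(self.absent_down)


def validate_against_panel(ts: TaggedSignature, panel: ReferencePanel) -> CoverageReport:
    """Report tag coverage against the panel gene universe.

    Raises if no tag at all is present (no score is computable then).
    """
    universe = set(panel.gene_ids)
    absent_up = tuple(g for g in ts.up_tags if g not in universe)
    absent_down = tuple(g for g in ts.down_tags if g not in universe)
    report = CoverageReport(
        present_up=len(ts.up_tags) - len(absent_up),
        present_down=len(ts.down_tags) - len(absent_down),
        absent_up=absent_up,
        absent_down=absent_down,
    )
    if report.present == 0:
        raise ValidationError("no signature tag is present in the panel gene universe")
    return report
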