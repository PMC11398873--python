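"""Building drug annotations and converting identifiers.

``ic50_to_labels`` turns a table of half-maximal inhibitory concentrations
(IC50, micromolar) into Effective/Ineffective labels for AUC-mode
benchmarking: a drug is Effective when its median IC50 falls strictly below
the threshold (default 10 uM); duplicates are collapsed by the median.
``convert_ids`` maps foreign gene/drug identifiers into a panel's universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .benchmark import EFFECTIVE, INEFFECTIVE, AnnotationSet
from .errors import InputError, ValidationError
from .signature import ReferencePanel

__all__ = ["ic50_to_labels", "convert_ids", "ConversionReport"]


def ic50_to_labels(
    table: pd.DataFrame | Sequence[tuple[str, float]], threshold: float = 10.0
) -> AnnotationSet:
    """Classify drugs by median IC50 against a potency threshold.

    ``table`` is a DataFrame with columns ``drug`` and ``ic50_um`` (or any
    sequence of (drug, ic50) pairs); multiple measurements per drug are
    allowed and summarized by the median. Drugs whose median is strictly
    below the threshold are labeled Effective; a median at or above it
    (including exactly at it) is Ineffective.
    """
    if threshold <= 0:
        raise ValidationError("IC50 threshold must be positive")
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table, columns=["drug", "ic50_um"])
    if not {"drug", "ic50_um"} <= set(table.columns):
        raise InputError("IC50 table needs 'drug' and 'ic50_um' columns")
    if len(table) == 0:
        raise InputError("IC50 table is empty")
    vals = pd.to_numeric(table["ic50_um"], errors="raise")
    if (vals <= 0).any():
        bad = table.loc[vals <= 0, "drug"].tolist()
        raise InputError(f"IC50 values must be positive; offending drugs: {bad[:5]}")
    medians = table.assign(ic50_um=vals).groupby("drug")["ic50_um"].median()
    labels = {
        str(d): (EFFECTIVE if v < threshold else INEFFECTIVE)
        for d, v in medians.items()
    }
    return AnnotationSet.from_labels(labels)


@dataclass(frozen=True)
class ConversionReport:
    """Outcome of an identifier conversion restricted to a panel."""

    converted: tuple[str, ...]  # mapped ids present in the panel, input order
    unmapped: tuple[str, ...]  # input ids with no mapping entry
    absent: tuple[str, ...]  # mapped ids not found in the panel universe


def convert_ids(
    items: Iterable[str],
    mapping: Mapping[str, str] | pd.DataFrame,
    panel: ReferencePanel,
) -> ConversionReport:
    """Map identifiers and keep only those present in the panel.

    The panel universe is the union of its gene and drug ids. Mapping keys
    must be unique; ids without a mapping entry are reported unmapped, and
    mapped ids missing from the panel are reported absent.
    """
    if isinstance(mapping, pd.DataFrame):
        if not {"old_id", "new_id"} <= set(mapping.columns):
            raise InputError("mapping table needs 'old_id' and 'new_id' columns")
        if mapping["old_id"].duplicated().any():
            dupes = mapping.loc[mapping["old_id"].duplicated(), "old_id"].tolist()
            raise InputError(f"duplicate old_id keys in mapping: {dupes[:5]}")
        mapping = dict(zip(mapping["old_id"].astype(str), mapping["new_id"].astype(str)))
    universe = set(panel.gene_ids) | set(panel.drug_ids)
    converted, unmapped, absent = [], [], []
    for item in items:
        item = str(item)
        if item not in mapping:
            unmapped.append(item)
        elif mapping[item] in universe:
            converted.append(mapping[item])
        else:
            absent.append(mapping[item])
    return ConversionReport(
        converted=tuple(converted), unmapped=tuple(unmapped), absent=tuple(absent)
    )
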