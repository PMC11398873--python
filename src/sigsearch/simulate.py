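"""Seeded synthetic panels, signatures, and annotations with planted structure.

The generator emulates an L1000-style screen at desk scale: a disease
signature with a block of genuinely differential genes, and a perturbation
panel of mostly noise columns into which a known subset of "effective"
drugs is planted as reversers (they shift the signature's differential
genes opposite to the disease direction by ``effect_size`` noise-standard-
deviations). Optional mimic columns shift the same genes *with* the
disease. Ground-truth labels are exported in both annotation modes, so
benchmarking, robustness and consensus querying are all testable without
any external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .benchmark import AnnotationSet
from .errors import ValidationError
from .signature import GeneSignature, ReferencePanel

__all__ = ["SimConfig", "make_signature", "make_panel"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated screen.

    Defaults mirror a small L1000-style dataset: 1000 landmark-scale genes,
    100 drugs of which 5 are true reversers, 250 differential genes per
    direction, a strong planted effect of 5 noise standard deviations, unit
    noise, and no planted mimics.
    """

    n_genes: int = 1000
    n_drugs: int = 100
    n_effective: int = 5
    n_deg: int = 250
    effect_size: float = 5.0
    noise_sd: float = 1.0
    mimic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_effective > self.n_drugs:
            raise ValidationError("n_effective cannot exceed n_drugs")
        if 2 * self.n_deg > self.n_genes:
            raise ValidationError("need 2 * n_deg <= n_genes")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if not 0 <= self.mimic_fraction <= 1:
            raise ValidationError("mimic_fraction must lie in [0, 1]")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _drug_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"drug{i:0{width}d}" for i in range(1, n + 1)]


def make_signature(cfg: SimConfig) -> GeneSignature:
    """Simulate a disease signature.

    A random block of ``n_deg`` genes is up-regulated and another block
    down-regulated, with magnitudes drawn from a shifted exponential and
    sorted so that |stat| decreases along each block (the strongest
    differential genes first); remaining genes get near-zero background
    stats. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    genes = np.array(_gene_ids(cfg.n_genes), dtype=object)
    perm = rng.permutation(cfg.n_genes)
    up_idx = perm[: cfg.n_deg]
    down_idx = perm[cfg.n_deg : 2 * cfg.n_deg]
    stats = rng.normal(0.0, 0.05, cfg.n_genes)
    up_mag = np.sort(rng.exponential(1.0, cfg.n_deg) + 0.5)[::-1]
    down_mag = np.sort(rng.exponential(1.0, cfg.n_deg) + 0.5)[::-1]
    stats[up_idx] = up_mag
    stats[down_idx] = -down_mag
    significant = np.zeros(cfg.n_genes, dtype=bool)
    significant[up_idx] = True
    significant[down_idx] = True
    return GeneSignature(
        genes=tuple(str(g) for g in genes),
        stats=tuple(float(s) for s in stats),
        significant=tuple(bool(b) for b in significant),
    )


def make_panel(
    cfg: SimConfig, sig: GeneSignature
) -> tuple[ReferencePanel, frozenset[str], tuple[AnnotationSet, AnnotationSet | None]]:
    """Simulate a perturbation panel with planted reversers.

    Background columns are iid Gaussian noise. ``n_effective`` randomly
    chosen drugs are planted as reversers: on the signature's differential
    genes they are shifted by ``-effect_size * noise_sd * sign(stat)``.
    ``round(mimic_fraction * n_effective)`` further background drugs are
    planted as mimics (shifted *with* the signature); mimics are labeled
    Ineffective. Returns the panel, the true effective set, and the
    ground-truth annotations in AUC mode and ES mode (the ES annotation is
    None when no drug is planted, since an empty effective set is invalid).
    """
    if set(sig.genes) != set(_gene_ids(cfg.n_genes)) and len(sig) != cfg.n_genes:
        raise ValidationError("signature gene universe does not match the config")
    rng = np.random.default_rng([cfg.seed, 1])
    genes = list(sig.genes)
    drugs = _drug_ids(cfg.n_drugs)
    mat = rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, cfg.n_drugs))

    stats = np.asarray(sig.stats, dtype=float)
    if sig.significant is not None:
        deg_mask = np.asarray(sig.significant, dtype=bool)
    else:
        deg_mask = stats != 0
    shift = cfg.effect_size * cfg.noise_sd * np.sign(stats) * deg_mask

    n_mimic = round(cfg.mimic_fraction * cfg.n_effective)
    planted = rng.choice(cfg.n_drugs, size=cfg.n_effective + n_mimic, replace=False)
    effective_idx = planted[: cfg.n_effective]
    mimic_idx = planted[cfg.n_effective :]
    for j in effective_idx:
        mat[:, j] -= shift
    for j in mimic_idx:
        mat[:, j] += shift

    panel = ReferencePanel(pd.DataFrame(mat, index=genes, columns=drugs))
    effective = frozenset(drugs[j] for j in sorted(effective_idx))
    labels = {d: ("Effective" if d in effective else "Ineffective") for d in drugs}
    ann_auc = AnnotationSet.from_labels(labels)
    ann_es = AnnotationSet.from_effective(effective) if effective else None
    return panel, effective, (ann_auc, ann_es)
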