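"""Pairwise linkage disequilibrium (genotype r-squared) and greedy pruning.

r-squared is the squared Pearson correlation of 0/1/2 genotype dosages
(composite LD), so unphased cohorts are supported; phased data may
optionally use haplotype D-based r-squared. Pruning is a deterministic
greedy scan in genomic order: a variant is kept iff its r-squared with every
previously kept variant on the same chromosome is below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .model import (
    GenotypeMatrix,
    InsufficientDataError,
    MonomorphicError,
    VariantKey,
)


@dataclass(frozen=True)
class LDResult:
    variant_a: VariantKey
    variant_b: VariantKey
    r_squared: float
    n_samples_used: int


def genotype_r2(dosages_a: Sequence[float], dosages_b: Sequence[float]) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Samples with a missing (NaN) value in either vector are excluded
    pairwise. Raises when fewer than two complete pairs remain or either
    vector is monomorphic among the remaining samples.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise InsufficientDataError("dosage vectors differ in length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise InsufficientDataError(
            f"only {a.size} complete pair(s); need at least 2"
        )
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise MonomorphicError("LD undefined: a variant is monomorphic among used samples")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def haplotype_r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Haplotype-level r-squared, D^2 / (p1 q1 p2 q2), for phased 0/1 vectors."""
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    p1, p2 = a.mean(), b.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise MonomorphicError("haplotype LD undefined for a monomorphic site")
    d = (a * b).mean() - p1 * p2
    return float(d * d / (p1 * (1 - p1) * p2 * (1 - p2)))


def _ordered(variants: Sequence[VariantKey], g: GenotypeMatrix) -> list:
    idx = [g.variant_index(v) for v in variants]
    order = sorted(
        range(len(idx)),
        key=lambda k: (variants[k].chrom, variants[k].pos, variants[k].ref, variants[k].alt),
    )
    return [(variants[k], idx[k]) for k in order]


def prune(
    g: GenotypeMatrix,
    variants: Sequence[VariantKey],
    threshold: float = 0.2,
    population: Optional[str] = None,
) -> list:
    """Greedy LD pruning; returns the kept variants in genomic order."""
    kept, _ = prune_with_reasons(g, variants, threshold, population)
    return kept


def prune_with_reasons(
    g: GenotypeMatrix,
    variants: Sequence[VariantKey],
    threshold: float = 0.2,
    population: Optional[str] = None,
) -> Tuple[list, list]:
    """Greedy LD pruning with, for each dropped variant, the kept partner.

    First-kept-wins in genomic position order (ties broken by allele
    strings). Cross-chromosome pairs are never compared, and pairs whose LD
    is undefined (monomorphic, or too few complete pairs) are treated as
    r-squared 0, i.e. never force a drop.
    """
    mask = g.population_mask(population)
    ordered = _ordered(variants, g)
    dosage = {j: g.dosage(j)[mask] for _, j in ordered}

    kept: list = []
    kept_idx: list = []
    dropped: list = []
    for v, j in ordered:
        partner = None
        r2_at = None
        for kv, kj in zip(kept, kept_idx):
            if kv.chrom != v.chrom:
                continue
            try:
                r2 = genotype_r2(dosage[kj], dosage[j])
            except (MonomorphicError, InsufficientDataError):
                continue
            if r2 >= threshold:
                partner, r2_at = kv, r2
                break
        if partner is None:
            kept.append(v)
            kept_idx.append(j)
        else:
            dropped.append((v, partner, r2_at))
    return kept, dropped
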