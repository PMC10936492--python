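"""Allele, carrier, haplotype and star-allele frequencies, and population
comparisons with Fisher's exact test and Benjamini-Hochberg FDR control.

Conventions that matter and are easy to get wrong:

* Allele frequency uses only non-missing calls: the denominator is the
  number of non-missing chromosomes, not 2n.
* Carrier frequency is the fraction of *individuals* with at least one copy
  (equals 1-(1-p)^2 under HWE); it is never interchanged with allele
  frequency even when a report prints both as "% of the population".
* The two-sided Fisher p follows the minimum-likelihood rule (sum of all
  table probabilities no larger than the observed table's) — the common
  convention, stated here because two-sided definitions differ.
* 2x2 counts derived from frequencies use ``round(af * n_chromosomes)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import match_effect_allele
from .model import (
    GenotypeMatrix,
    ParameterError,
    StarAlleleDefinition,
    UndefinedFrequencyError,
    VariantKey,
)


@dataclass(frozen=True)
class FrequencyRecord:
    variant: VariantKey
    population: str
    effect_allele: str
    af: float
    n_chromosomes: int


@dataclass
class ComparisonResult:
    variant: VariantKey
    population_a: str
    population_b: str
    odds_ratio: float  # NaN when 0/0-undefined
    p_value: float
    q_value: Optional[float] = None
    significant: Optional[bool] = None


def _allele_index(v: VariantKey, allele: str) -> int:
    idx = match_effect_allele(v, allele)
    if idx is None:
        raise ParameterError(
            f"allele {allele!r} matches neither ref nor alt of {v.vid}"
        )
    return idx


def allele_frequency(
    g: GenotypeMatrix, v: VariantKey, allele: str, population: Optional[str] = None
) -> FrequencyRecord:
    """Frequency of ``allele`` among non-missing chromosomes of a population."""
    j = g.variant_index(v)
    idx = _allele_index(v, allele)
    mask = g.population_mask(population)
    calls = g.alleles[mask][:, j, :]
    nonmissing = calls >= 0
    n_chrom = int(nonmissing.sum())
    if n_chrom == 0:
        raise UndefinedFrequencyError(
            f"every call is missing for {v.vid} in population {population!r}"
        )
    count = int((calls[nonmissing] == idx).sum())
    return FrequencyRecord(
        variant=v,
        population=population or "all",
        effect_allele=allele.upper(),
        af=count / n_chrom,
        n_chromosomes=n_chrom,
    )


def carrier_frequency(
    g: GenotypeMatrix, v: VariantKey, allele: str, population: Optional[str] = None
) -> float:
    """Fraction of individuals carrying >=1 copy, among non-missing samples."""
    j = g.variant_index(v)
    idx = _allele_index(v, allele)
    mask = g.population_mask(population)
    calls = g.alleles[mask][:, j, :]
    complete = (calls >= 0).all(axis=1)
    if not complete.any():
        raise UndefinedFrequencyError(
            f"every call is missing for {v.vid} in population {population!r}"
        )
    carriers = (calls[complete] == idx).any(axis=1)
    return float(carriers.mean())


def haplotype_star_frequency(
    g: GenotypeMatrix,
    definitions: Sequence[StarAlleleDefinition],
    population: Optional[str] = None,
    other_label: str = "reference/other",
) -> dict:
    """Assign phased haplotypes to star alleles; first matching definition wins.

    Definition files should order suballeles from most to least specific,
    since an ambiguous haplotype goes to the earliest definition whose
    required alleles all match. Unassigned haplotypes are pooled under
    ``other_label``.
    """
    mask = g.population_mask(population)
    needed = []
    for d in definitions:
        for key, _ in d.defining_alleles:
            j = g.variant_index(key)
            if j not in needed:
                needed.append(j)
    haps = g.haplotypes(needed, mask)  # raises PhaseError on unphased calls
    col_of = {j: c for c, j in enumerate(needed)}

    n_hap = haps.shape[0]
    counts = {d.star_name: 0 for d in definitions}
    unassigned = 0
    for h in range(n_hap):
        for d in definitions:
            ok = True
            for key, required in d.defining_alleles:
                idx = _allele_index(key, required)
                if haps[h, col_of[g.variant_index(key)]] != idx:
                    ok = False
                    break
            if ok:
                counts[d.star_name] += 1
                break
        else:
            unassigned += 1
    out = {name: c / n_hap for name, c in counts.items()}
    out[other_label] = unassigned / n_hap
    return out


def compare_frequencies(
    count_a: Tuple[int, int], count_b: Tuple[int, int]
) -> Tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table [[a_eff, a_oth], [b_eff, b_oth]].

    Returns ``(odds_ratio, p_value)``. The odds ratio is the sample
    (ad)/(bc) cross-product, ``inf`` when only the denominator is zero and
    NaN for the 0/0-undefined case.
    """
    a, b = count_a
    c, d = count_b
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ParameterError(f"counts must be non-negative integers, got {x!r}")
    if a + b == 0 or c + d == 0:
        raise ParameterError("both row margins must be positive")
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    num, den = a * d, b * c
    if den > 0:
        oratio = num / den
    elif num > 0:
        oratio = math.inf
    else:
        oratio = math.nan
    return oratio, float(p)


def counts_from_frequency(af: float, n_chromosomes: int) -> Tuple[int, int]:
    """(effect, other) chromosome counts implied by a frequency; rounded once."""
    if not 0.0 <= af <= 1.0:
        raise ParameterError("allele frequency must lie in [0, 1]")
    effect = int(round(af * n_chromosomes))
    return effect, n_chromosomes - effect


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ParameterError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def compare_population_frequencies(
    g: GenotypeMatrix,
    panel: Sequence[Tuple[VariantKey, str]],
    reference_population: str,
    alpha: float = 0.05,
    family: str = "all",
) -> list:
    """Fisher-compare the reference population against every other population.

    ``panel`` is (variant, effect allele) pairs. The FDR family defaults to
    every variant x population-pair comparison computed in this invocation
    (figure-wide correction); ``family="per_population"`` adjusts within each
    population pair instead.
    """
    if family not in ("all", "per_population"):
        raise ParameterError("family must be 'all' or 'per_population'")
    others = sorted(set(g.populations) - {reference_population})
    if not others:
        raise ParameterError("need at least two populations to compare")
    results = []
    for v, allele in panel:
        fa = allele_frequency(g, v, allele, reference_population)
        ca = counts_from_frequency(fa.af, fa.n_chromosomes)
        for pop in others:
            fb = allele_frequency(g, v, allele, pop)
            cb = counts_from_frequency(fb.af, fb.n_chromosomes)
            oratio, p = compare_frequencies(ca, cb)
            results.append(
                ComparisonResult(
                    variant=v,
                    population_a=reference_population,
                    population_b=pop,
                    odds_ratio=oratio,
                    p_value=p,
                )
            )
    if family == "all":
        q = fdr_adjust([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
            r.significant = bool(qv < alpha)
    else:
        for pop in others:
            grp = [r for r in results if r.population_b == pop]
            q = fdr_adjust([r.p_value for r in grp])
            for r, qv in zip(grp, q):
                r.q_value = float(qv)
                r.significant = bool(qv < alpha)
    return results
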