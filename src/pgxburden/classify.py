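"""Direction classification of clinical annotations and deleteriousness filters.

The direction of an annotation refers to its stated effect allele (not the
population-relative minor allele, which is unstable under resampling):
``increased response`` marks a positive (improved-outcome) allele and
``decreased response`` a negative one. When efficacy and toxicity terms
co-occur, the efficacy term decides. Toxicity-only annotations are kept and
signed by toxicity (decreased toxicity = positive) unless ``efficacy_only``
is set. Dosage/PK phenotypes normalize to ``other`` and are excluded from
burden scoring but retained in reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .model import (
    ClinicalAnnotation,
    DrugGeneMap,
    IndeterminateError,
    ParameterError,
    VariantKey,
    VerdictRow,
)

log = logging.getLogger(__name__)

EFFICACY_TERMS = {"increased response": "positive", "decreased response": "negative"}
TOXICITY_TERMS = {"decreased toxicity": "positive", "increased toxicity": "negative"}


@dataclass(frozen=True)
class DirectionalAnnotation:
    base: ClinicalAnnotation
    direction: str  # positive | negative | excluded
    rationale: str  # efficacy_term | toxicity_only | conflict_resolved |
    #                 toxicity_only_ambiguous | unmappable


@dataclass(frozen=True)
class DeleteriousCall:
    variant: VariantKey
    n_tools_deleterious: int
    consensus: bool
    effect_af: float
    common: bool
    gene: Optional[str] = None


def classify_direction(
    a: ClinicalAnnotation, efficacy_only: bool = False
) -> DirectionalAnnotation:
    """Classify one annotation as positive, negative or excluded.

    Every input is classified; exclusions carry a rationale code rather than
    raising, so the output always partitions the input set.
    """
    terms = {t.strip().lower() for t in a.phenotype_terms}
    eff = {EFFICACY_TERMS[t] for t in terms & EFFICACY_TERMS.keys()}
    tox = {TOXICITY_TERMS[t] for t in terms & TOXICITY_TERMS.keys()}

    if eff:
        if len(eff) > 1:
            return DirectionalAnnotation(a, "excluded", "unmappable")
        rationale = "conflict_resolved" if tox else "efficacy_term"
        return DirectionalAnnotation(a, next(iter(eff)), rationale)
    if tox and not efficacy_only:
        if len(tox) > 1:
            return DirectionalAnnotation(a, "excluded", "toxicity_only_ambiguous")
        return DirectionalAnnotation(a, next(iter(tox)), "toxicity_only")
    return DirectionalAnnotation(a, "excluded", "unmappable")


def classify_directions(
    annotations: Sequence[ClinicalAnnotation], efficacy_only: bool = False
) -> list:
    return [classify_direction(a, efficacy_only) for a in annotations]


def consensus_deleterious(row: VerdictRow, min_tools: int = 2) -> bool:
    """True iff at least ``min_tools`` tools call the variant deleterious.

    Missing verdicts count as neither deleterious nor tolerated; a row where
    every tool is missing is indeterminate and raises.
    """
    if min_tools < 1:
        raise ParameterError("min_tools must be >= 1")
    non_missing = [v for v in row.verdicts if v != "missing"]
    if not non_missing:
        raise IndeterminateError(
            f"all verdicts missing for {row.variant.vid}; consensus indeterminate"
        )
    return sum(v == "deleterious" for v in non_missing) >= min_tools


def filter_common_deleterious(
    calls: Sequence[DeleteriousCall], af_threshold: float = 0.01
) -> list:
    """Retain consensus-deleterious calls with effect AF strictly above threshold."""
    return [c for c in calls if c.consensus and c.effect_af > af_threshold]


def map_to_pharmacogenes(
    variants: Sequence, dmap: DrugGeneMap
) -> pd.DataFrame:
    """Inner-join gene-labelled variants against the drug-gene map.

    ``variants`` are (VariantKey, gene) pairs. Variants whose gene is in no
    pharmacogene entry are dropped, with the count logged. A gene serving
    several drugs yields one row per (drug, role).
    """
    rows = []
    dropped = 0
    gene_entries: dict = {}
    for drug, gene, role in dmap.entries:
        gene_entries.setdefault(gene, []).append((drug, role))
    for v, gene in variants:
        hits = gene_entries.get(gene)
        if not hits:
            dropped += 1
            continue
        for drug, role in sorted(hits):
            rows.append(
                {
                    "variant": v.vid,
                    "rsid": v.rsid or "",
                    "gene": gene,
                    "drug": drug,
                    "role": role,
                    "drug_class": dmap.categories[drug],
                }
            )
    if dropped:
        log.info("map_to_pharmacogenes: %d variant(s) in no pharmacogene dropped", dropped)
    return pd.DataFrame(
        rows, columns=["variant", "rsid", "gene", "drug", "role", "drug_class"]
    )
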