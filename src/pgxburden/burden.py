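"""Per-individual cumulative effect-allele burden and cross-population tests.

For each drug class, positive- and negative-direction effect-allele dosages
are summed separately within each individual over the (LD-pruned) panel,
and the imbalance negative - positive is derived. Population location
differences are tested with Kruskal-Wallis (omnibus) and a two-sided
rank-sum (unpaired Wilcoxon) test of a reference population against each
other population. A variant annotated for several drugs of one class counts
once per class; the same variant may count in several classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classify import DirectionalAnnotation
from .frequency import fdr_adjust
from .io_formats import match_effect_allele
from .model import GenotypeMatrix, ParameterError, VariantKey

log = logging.getLogger(__name__)

PROFILE_COLUMNS = [
    "sample",
    "population",
    "drug_class",
    "positive_count",
    "negative_count",
    "imbalance",
    "n_variants_used",
    "n_missing",
    "high_missingness",
]


def burden_profile(
    g: GenotypeMatrix,
    panel: Sequence[DirectionalAnnotation],
    missingness_flag: float = 0.2,
) -> pd.DataFrame:
    """Per-sample, per-drug-class positive/negative effect-allele counts.

    Missing calls contribute 0 to the counts (no imputation) and increment
    ``n_missing``; samples exceeding ``missingness_flag`` fraction of the
    class panel missing are flagged, not dropped. Classes with an empty
    usable panel are skipped with a warning.
    """
    by_class: Dict[str, set] = {}
    for d in panel:
        if d.direction not in ("positive", "negative"):
            raise ParameterError(
                f"burden panel must be direction-classified; got {d.direction!r}"
            )
        if not isinstance(d.base.variant, VariantKey):
            raise ParameterError(
                f"burden panel variant {d.base.variant!r} is not genotype-addressable"
            )
        by_class.setdefault(d.base.drug_class, set()).add(
            (d.base.variant, d.base.effect_allele, d.direction)
        )

    rows = []
    for drug_class in sorted(by_class):
        entries = sorted(by_class[drug_class], key=lambda e: (e[0].vid, e[2]))
        usable = []
        for v, allele, direction in entries:
            idx = match_effect_allele(v, allele)
            if idx is None:
                log.warning(
                    "burden: effect allele %s matches neither allele of %s; skipped",
                    allele,
                    v.vid,
                )
                continue
            usable.append((g.variant_index(v), idx, direction))
        if not usable:
            log.warning("burden: class %s has an empty usable panel; skipped", drug_class)
            continue
        n = g.n_samples
        pos = np.zeros(n, dtype=int)
        neg = np.zeros(n, dtype=int)
        missing = np.zeros(n, dtype=int)
        for j, allele_idx, direction in usable:
            calls = g.alleles[:, j, :]
            miss = (calls == -1).any(axis=1)
            dose = (calls == allele_idx).sum(axis=1)
            dose[miss] = 0
            missing += miss.astype(int)
            if direction == "positive":
                pos += dose
            else:
                neg += dose
        for i in range(n):
            rows.append(
                {
                    "sample": g.samples[i],
                    "population": g.populations[i],
                    "drug_class": drug_class,
                    "positive_count": int(pos[i]),
                    "negative_count": int(neg[i]),
                    "imbalance": int(neg[i] - pos[i]),
                    "n_variants_used": len(usable),
                    "n_missing": int(missing[i]),
                    "high_missingness": bool(missing[i] > missingness_flag * len(usable)),
                }
            )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


@dataclass
class BurdenComparison:
    drug_class: str
    direction_panel: str  # positive | negative | imbalance
    kruskal_wallis_p: float
    pairwise: Dict[Tuple[str, str], float] = field(default_factory=dict)
    pairwise_q: Dict[Tuple[str, str], float] = field(default_factory=dict)


def rank_sum_p(x: Sequence[float], y: Sequence[float], exact_max_n: int = 50) -> float:
    """Two-sided unpaired rank-sum p-value.

    Exact enumeration when both groups have at most ``exact_max_n``
    observations and there are no ties; otherwise the normal approximation
    with midranks, tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0  # degenerate: identical constants carry no ordering signal
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def compare_burden(
    profiles: pd.DataFrame,
    reference_population: str,
    min_group: int = 2,
) -> list:
    """Omnibus and reference-vs-other location tests per class and panel.

    Populations with fewer than ``min_group`` profiles are excluded with a
    warning. With fewer than three populations the Kruskal-Wallis omnibus is
    reported as NaN; pairwise tests only need two. Pairwise p-values are
    reported unadjusted (no pairwise correction is applied by default), with
    a BH-adjusted column alongside.
    """
    results = []
    for drug_class, sub in profiles.groupby("drug_class", sort=True):
        sizes = sub.groupby("population").size()
        ok_pops = sorted(sizes[sizes >= min_group].index)
        for pop in sorted(set(sub["population"]) - set(ok_pops)):
            log.warning(
                "compare_burden: population %s has <%d profiles in class %s; excluded",
                pop, min_group, drug_class,
            )
        if reference_population not in ok_pops or len(ok_pops) < 2:
            log.warning(
                "compare_burden: class %s lacks a comparable reference group; skipped",
                drug_class,
            )
            continue
        for panel in ("positive_count", "negative_count", "imbalance"):
            groups = {
                p: sub.loc[sub["population"] == p, panel].to_numpy(dtype=float)
                for p in ok_pops
            }
            if len(ok_pops) >= 3:
                pooled = np.concatenate(list(groups.values()))
                if np.ptp(pooled) == 0:
                    kw_p = 1.0
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        kw_p = float(stats.kruskal(*groups.values()).pvalue)
            else:
                kw_p = float("nan")
            comp = BurdenComparison(
                drug_class=drug_class,
                direction_panel={"positive_count": "positive", "negative_count": "negative"}.get(panel, panel),
                kruskal_wallis_p=kw_p,
            )
            pairs = [
                (reference_population, p) for p in ok_pops if p != reference_population
            ]
            for pair in pairs:
                comp.pairwise[pair] = rank_sum_p(groups[pair[0]], groups[pair[1]])
            qs = fdr_adjust(list(comp.pairwise.values()))
            comp.pairwise_q = {k: float(q) for k, q in zip(comp.pairwise, qs)}
            results.append(comp)
    return results


def comparisons_to_frame(comparisons: Sequence[BurdenComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        for (ref, other), p in c.pairwise.items():
            rows.append(
                {
                    "drug_class": c.drug_class,
                    "direction_panel": c.direction_panel,
                    "kruskal_wallis_p": c.kruskal_wallis_p,
                    "population_a": ref,
                    "population_b": other,
                    "wilcoxon_p": p,
                    "wilcoxon_q": c.pairwise_q[(ref, other)],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "drug_class",
            "direction_panel",
            "kruskal_wallis_p",
            "population_a",
            "population_b",
            "wilcoxon_p",
            "wilcoxon_q",
        ],
    )
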