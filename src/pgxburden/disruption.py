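"""Drug-function disruption from common deleterious variants.

A pharmacogene is "disrupted" when it carries at least one consensus-
deleterious variant common in the cohort. Each drug's three function roles
(target, enzyme, transporter) are evaluated independently: a role is
completely disrupted when every one of the drug's role-genes is disrupted,
and partially disrupted when at least half are, in both cases requiring the
disruption to occur above the frequency floor ``af_min``.

Gene-level frequency aggregates multiple disrupting variants by maximum AF
by default (conservative, mirrors per-variant reporting); the combined mode
``1 - prod(1 - af_i)`` approximates the any-disrupting-allele haplotype
frequency under independence. Disruption prevalence is expressed as allele
frequency in the flag logic; carrier frequency is reported alongside when
genotypes are available, and the two are never conflated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import DeleteriousCall
from .model import DrugGeneMap, ParameterError, FUNCTION_ROLES


@dataclass(frozen=True)
class GeneDisruption:
    gene: str
    disrupting_variants: tuple  # of (VariantKey, effect_af)
    gene_af: float


@dataclass(frozen=True)
class DisruptionReport:
    drug: str
    function_role: str
    n_genes_total: int
    n_genes_disrupted: int
    fraction_disrupted: float
    max_gene_af: float
    complete_flag: bool
    partial_flag: bool


def gene_disruption(
    calls: Sequence[DeleteriousCall], mode: str = "max"
) -> list:
    """Group common deleterious calls by gene and aggregate their AFs.

    ``calls`` must already have passed the consensus and common-AF filters
    and carry gene labels. Genes with no qualifying variant are simply
    absent from the output.
    """
    if mode not in ("max", "combined"):
        raise ParameterError("mode must be 'max' or 'combined'")
    by_gene: Dict[str, list] = {}
    for c in calls:
        if c.gene is None:
            raise ParameterError(f"call {c.variant.vid} lacks a gene label")
        by_gene.setdefault(c.gene, []).append(c)
    out = []
    for gene in sorted(by_gene):
        members = sorted(by_gene[gene], key=lambda c: c.variant.vid)
        afs = np.array([c.effect_af for c in members])
        gene_af = float(afs.max()) if mode == "max" else float(1 - np.prod(1 - afs))
        out.append(
            GeneDisruption(
                gene=gene,
                disrupting_variants=tuple((c.variant, c.effect_af) for c in members),
                gene_af=gene_af,
            )
        )
    return out


def disruption_report(
    dmap: DrugGeneMap,
    disruptions: Sequence[GeneDisruption],
    af_min: float = 0.01,
) -> list:
    """Per (drug, role): fraction of role-genes disrupted above ``af_min``.

    A (drug, role) with zero genes is omitted, never counted as disrupted.
    ``complete_flag`` requires every role-gene disrupted; ``partial_flag``
    at least half. Both require disruption frequency strictly above
    ``af_min``, which holds by construction since only genes with
    ``gene_af > af_min`` count as disrupted.
    """
    af_of = {d.gene: d.gene_af for d in disruptions}
    reports = []
    for drug in dmap.drugs():
        for role in FUNCTION_ROLES:
            genes = sorted(dmap.genes(drug=drug, role=role))
            if not genes:
                continue
            hit_afs = [af_of[g] for g in genes if af_of.get(g, 0.0) > af_min]
            n_dis = len(hit_afs)
            fraction = n_dis / len(genes)
            max_af = max(hit_afs) if hit_afs else 0.0
            reports.append(
                DisruptionReport(
                    drug=drug,
                    function_role=role,
                    n_genes_total=len(genes),
                    n_genes_disrupted=n_dis,
                    fraction_disrupted=fraction,
                    max_gene_af=max_af,
                    complete_flag=fraction == 1.0,
                    partial_flag=fraction >= 0.5 and n_dis > 0,
                )
            )
    return reports


def sankey_table(
    reports: Sequence[DisruptionReport],
    dmap: DrugGeneMap,
    disruptions: Sequence[GeneDisruption],
) -> pd.DataFrame:
    """Drug -> gene -> function flow rows weighted by gene AF (plot-ready)."""
    af_of = {d.gene: d.gene_af for d in disruptions}
    reported = {(r.drug, r.function_role) for r in reports}
    rows = []
    for drug, gene, role in sorted(dmap.entries):
        if (drug, role) not in reported or gene not in af_of:
            continue
        rows.append(
            {"drug": drug, "gene": gene, "function_role": role, "weight": af_of[gene]}
        )
    return pd.DataFrame(rows, columns=["drug", "gene", "function_role", "weight"])


def reports_to_frame(reports: Sequence[DisruptionReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": r.drug,
                "function_role": r.function_role,
                "n_genes_total": r.n_genes_total,
                "n_genes_disrupted": r.n_genes_disrupted,
                "fraction_disrupted": r.fraction_disrupted,
                "max_gene_af": r.max_gene_af,
                "complete_flag": r.complete_flag,
                "partial_flag": r.partial_flag,
            }
            for r in reports
        ],
        columns=[
            "drug",
            "function_role",
            "n_genes_total",
            "n_genes_disrupted",
            "fraction_disrupted",
            "max_gene_af",
            "complete_flag",
            "partial_flag",
        ],
    )
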