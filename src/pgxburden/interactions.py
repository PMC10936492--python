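"""Gene sharing between drug categories, drug-gene networks, inhibitor-based
DDI prediction, and rule-based DDGI classification.

DDGI categories follow the standard three-way scheme: category 1 magnifies a
drug-drug interaction on the same metabolic pathway (the genetic phenotype
and the perpetrator's action push the same pathway in the same direction),
category 2 magnifies it across different pathways of the same victim drug,
and category 3 covers opposing effects (e.g. an ultrarapid-metabolizer
phenotype on a pathway the perpetrator inhibits). Classification is
pathway-topology-based only; inhibitor strength tiers annotate predictions
but never change the category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

from .model import DrugGeneMap, InhibitionRecord, ParameterError

#: metabolizer / transporter phenotype -> activity sign
PHENOTYPE_SIGN = {
    "PM": -1,  # poor metabolizer
    "IM": -1,  # intermediate metabolizer
    "NM": 0,   # normal metabolizer
    "UM": +1,  # ultrarapid metabolizer
    "decreased": -1,
    "normal": 0,
}


@dataclass(frozen=True)
class OverlapSummary:
    category: str
    n_genes: int
    n_shared_with_niads: int
    overlap_fraction: float
    intersection_all_categories: frozenset


@dataclass
class DrugGeneNetwork:
    graph: nx.Graph
    gene_degree: Dict[str, int]
    drug_share_score: Dict[str, float]


@dataclass(frozen=True)
class DDGIPrediction:
    victim: str
    perpetrator: str
    gene: str
    phenotype: str
    category: object  # 1 | 2 | 3 | "none"
    rationale: str


def overlap_analysis(dmap: DrugGeneMap, niad_category: str) -> list:
    """Gene-set overlap of each co-medication category with the NIAD genes.

    The overlap fraction's denominator is the co-medication category's gene
    set (so "71% of PPI genes are also NIAD genes" style statements).
    Duplicate map rows cannot inflate anything: the map has set semantics.
    """
    categories = sorted(set(dmap.categories.values()))
    if niad_category not in categories:
        raise ParameterError(f"category {niad_category!r} absent from the map")
    if len(categories) < 2:
        raise ParameterError("need at least two categories to overlap")
    niad_genes = dmap.category_genes(niad_category)
    all_sets = [dmap.category_genes(c) for c in categories if dmap.category_genes(c)]
    intersection_all = frozenset(set.intersection(*all_sets)) if all_sets else frozenset()
    out = []
    for cat in categories:
        if cat == niad_category:
            continue
        genes = dmap.category_genes(cat)
        if not genes:
            continue
        shared = genes & niad_genes
        out.append(
            OverlapSummary(
                category=cat,
                n_genes=len(genes),
                n_shared_with_niads=len(shared),
                overlap_fraction=len(shared) / len(genes),
                intersection_all_categories=intersection_all,
            )
        )
    return out


def build_network(dmap: DrugGeneMap) -> DrugGeneNetwork:
    """Bipartite drug-gene graph with gene degree and drug share scores.

    A gene's degree is its number of incident drugs. A drug's share score is
    the fraction of its genes that are shared with at least one drug of a
    different category (0 when no other category exists).
    """
    if len(dmap) == 0:
        raise ParameterError("drug-gene map is empty")
    graph = nx.Graph()
    for drug in dmap.drugs():
        graph.add_node(drug, kind="drug", category=dmap.categories[drug])
    edges = {(d, g) for d, g, _ in dmap.entries}
    for d, g in edges:
        if not graph.has_node(g):
            graph.add_node(g, kind="gene")
        graph.add_edge(d, g)

    gene_degree = {
        n: graph.degree(n) for n, a in graph.nodes(data=True) if a["kind"] == "gene"
    }
    cats_of_gene: Dict[str, Set[str]] = {}
    for d, g in edges:
        cats_of_gene.setdefault(g, set()).add(dmap.categories[d])
    drug_share_score = {}
    for drug in dmap.drugs():
        genes = dmap.genes(drug=drug)
        my_cat = dmap.categories[drug]
        shared = {g for g in genes if cats_of_gene[g] - {my_cat}}
        drug_share_score[drug] = len(shared) / len(genes) if genes else 0.0
    return DrugGeneNetwork(graph, gene_degree, drug_share_score)


def inhibitor_join(
    dmap: DrugGeneMap, inhibitors: Sequence[InhibitionRecord]
) -> pd.DataFrame:
    """Predicted DDIs: perpetrators inhibiting an enzyme of a victim drug.

    One row per (victim, perpetrator, enzyme) where the perpetrator inhibits
    an enzyme in the victim's enzyme-role gene set; self-pairs excluded.
    """
    rows = []
    for victim in dmap.drugs():
        enzymes = dmap.genes(drug=victim, role="enzyme")
        for rec in inhibitors:
            if rec.action != "inhibit":
                continue
            if rec.enzyme in enzymes and rec.drug != victim:
                rows.append(
                    {
                        "victim": victim,
                        "perpetrator": rec.drug,
                        "enzyme": rec.enzyme,
                        "strength": rec.strength,
                    }
                )
    return pd.DataFrame(rows, columns=["victim", "perpetrator", "enzyme", "strength"])


def classify_ddgi(
    victim: str,
    perpetrator: str,
    victim_pathways: Dict[str, float],
    perpetrator_actions: Sequence[InhibitionRecord],
    phenotype: Tuple[str, str],
    major_threshold: float = 0.5,
) -> DDGIPrediction:
    """Classify one (victim, perpetrator, phenotype) triple into DDGI categories.

    ``victim_pathways`` maps each metabolizing enzyme (or transporter) of the
    victim to its contribution fraction (must sum to at most 1).
    ``phenotype`` is ``(gene, class)`` with class in PM/IM/NM/UM or
    decreased/normal. Rules, in precedence order:

    1. category 1 — the phenotype gene lies in the victim's pathway set and
       the perpetrator pushes that same pathway in the same direction as the
       phenotype (inhibition with a reduced-activity phenotype, or induction
       with an increased-activity one): same-pathway magnification.
    2. category 3 — the perpetrator pushes the phenotype gene's pathway in
       the opposite direction (inhibits a pathway with increased genetic
       activity, or induces one with reduced activity): opposing effects.
    3. category 2 — the phenotype reduces (or increases) one pathway while
       the perpetrator pushes a *different* pathway of the same victim in
       the same direction: different-pathway magnification.
    4. none otherwise (including normal-activity phenotypes and phenotype
       genes outside the victim's pathway set).
    """
    total = sum(victim_pathways.values())
    if total > 1 + 1e-9:
        raise ParameterError(f"pathway contributions sum to {total:.3f} > 1")
    for frac in victim_pathways.values():
        if not 0.0 <= frac <= 1.0:
            raise ParameterError("contribution fractions must lie in [0, 1]")
    gene, pclass = phenotype
    if pclass not in PHENOTYPE_SIGN:
        raise ParameterError(f"unknown phenotype class {pclass!r}")
    sign = PHENOTYPE_SIGN[pclass]
    pheno = f"{gene} {pclass}"

    if gene not in victim_pathways:
        return DDGIPrediction(
            victim, perpetrator, gene, pclass, "none",
            f"{pheno}: gene not in {victim}'s pathway set",
        )
    if sign == 0:
        return DDGIPrediction(
            victim, perpetrator, gene, pclass, "none",
            f"{pheno}: normal-activity phenotype",
        )

    inhibited = {
        r.enzyme for r in perpetrator_actions
        if r.drug == perpetrator and r.action == "inhibit" and r.enzyme in victim_pathways
    }
    induced = {
        r.enzyme for r in perpetrator_actions
        if r.drug == perpetrator and r.action == "induce" and r.enzyme in victim_pathways
    }
    same_direction = inhibited if sign < 0 else induced
    opposite_direction = induced if sign < 0 else inhibited
    weight = "major" if victim_pathways[gene] >= major_threshold else "minor"

    if gene in same_direction:
        action = "inhibits" if sign < 0 else "induces"
        return DDGIPrediction(
            victim, perpetrator, gene, pclass, 1,
            f"{perpetrator} {action} {gene} ({weight} pathway of {victim}) and "
            f"{pheno} reinforces it on the same pathway",
        )
    if gene in opposite_direction:
        action = "induces" if sign < 0 else "inhibits"
        return DDGIPrediction(
            victim, perpetrator, gene, pclass, 3,
            f"{perpetrator} {action} {gene} while {pheno} acts in the opposite "
            f"direction on the same pathway",
        )
    others = sorted(same_direction - {gene})
    if others:
        action = "inhibits" if sign < 0 else "induces"
        return DDGIPrediction(
            victim, perpetrator, gene, pclass, 2,
            f"{perpetrator} {action} {', '.join(others)} while {pheno} affects a "
            f"different ({weight}) pathway of {victim}",
        )
    return DDGIPrediction(
        victim, perpetrator, gene, pclass, "none",
        f"{perpetrator} does not act on {victim}'s pathways in a combining direction",
    )


def network_to_json(net: DrugGeneNetwork) -> dict:
    """Node-link JSON (generic graph interchange, importable by viewers)."""
    graph = net.graph.copy()
    for gene, deg in net.gene_degree.items():
        graph.nodes[gene]["degree"] = deg
    for drug, score in net.drug_share_score.items():
        graph.nodes[drug]["share_score"] = score
    return nx.node_link_data(graph, edges="links")


def network_edge_list(net: DrugGeneNetwork) -> pd.DataFrame:
    rows = [
        {"drug": d, "gene": g}
        for d, g in sorted(net.graph.edges())
        if net.graph.nodes[d]["kind"] == "drug"
    ]
    rows += [
        {"drug": g, "gene": d}
        for d, g in sorted(net.graph.edges())
        if net.graph.nodes[d]["kind"] == "gene"
    ]
    return pd.DataFrame(sorted(rows, key=lambda r: (r["drug"], r["gene"])), columns=["drug", "gene"])
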