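"""Synthetic multi-population diploid cohorts with known ground truth.

Genotypes are drawn under Hardy-Weinberg equilibrium: each individual is two
independent haplotypes, and each haplotype carries Bernoulli(af) alleles at
unlinked sites. Linkage-disequilibrium blocks are generated at the haplotype
level with a first-order chain whose transition probabilities are chosen to
hit a target pairwise correlation r between adjacent members; haplotypes are
then paired into (phased) diploids. The generator also emits matched clinical
annotations, drug-gene maps and in-silico verdict tables whose true
directions and deleteriousness are recorded as ground truth, standing in for
the cohort-and-database inputs of a real population survey.

Reproducibility: one global integer seed drives a named sub-stream per
population and per table, so adding a population never perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .model import (
    DrugGeneMap,
    GenotypeMatrix,
    ClinicalAnnotation,
    ParameterError,
    VariantKey,
    VerdictRow,
    VerdictTable,
)

#: drug classes used for synthetic annotation suites
NIAD_CLASSES = (
    "biguanide",
    "sulfonylurea",
    "thiazolidinedione",
    "dpp4_inhibitor",
    "glp1_analog",
    "sglt2_inhibitor",
    "meglitinide",
    "alpha_glucosidase_inhibitor",
)


@dataclass
class PopulationSpec:
    """One population's size and per-variant effect-allele frequencies."""

    name: str
    n_individuals: int
    af_vector: Sequence[float]

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ParameterError("n_individuals must be positive")
        af = np.asarray(self.af_vector, dtype=float)
        if af.ndim != 1:
            raise ParameterError("af_vector must be one-dimensional")
        if ((af < 0) | (af > 1)).any():
            raise ParameterError("allele frequencies must lie in [0, 1]")
        self.af_vector = af


@dataclass
class LDBlockSpec:
    """An ordered run of panel indices with a target adjacent-pair haplotype r."""

    member_variants: Sequence[int]
    target_r: float

    def __post_init__(self) -> None:
        members = list(self.member_variants)
        if len(members) != len(set(members)):
            raise ParameterError("LD block members must be distinct")
        if len(members) < 2:
            raise ParameterError("an LD block needs at least two members")
        if not -1.0 <= self.target_r <= 1.0:
            raise ParameterError("target_r must lie in [-1, 1]")
        self.member_variants = members


@dataclass
class GroundTruth:
    """What the generator knows: the recovery-test oracle."""

    true_af: Dict[str, Dict[str, float]] = field(default_factory=dict)
    direction: Dict[str, str] = field(default_factory=dict)
    deleterious: List[str] = field(default_factory=list)
    gene_disrupted: Dict[str, bool] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "true_af": self.true_af,
                    "direction": self.direction,
                    "deleterious": sorted(self.deleterious),
                    "gene_disrupted": self.gene_disrupted,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child RNG stream."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


def feasible_r_bounds(p1: float, p2: float) -> tuple:
    """Frechet bounds on the haplotype correlation for two allele frequencies."""
    q1, q2 = 1 - p1, 1 - p2
    denom = np.sqrt(p1 * q1 * p2 * q2)
    if denom == 0:
        return (0.0, 0.0)
    lo = (max(0.0, p1 + p2 - 1) - p1 * p2) / denom
    hi = (min(p1, p2) - p1 * p2) / denom
    return (lo, hi)


def default_variant_panel(n_variants: int, chrom: str = "1", spacing: int = 1000) -> list:
    """Evenly spaced synthetic biallelic SNVs on one chromosome."""
    bases = ("A", "C", "G", "T")
    panel = []
    for j in range(n_variants):
        ref = bases[j % 4]
        alt = bases[(j + 1) % 4]
        panel.append(
            VariantKey(chrom, (j + 1) * spacing, ref, alt, rsid=f"rs{900000 + j}")
        )
    return panel


def simulate_cohort(
    specs: Sequence[PopulationSpec],
    blocks: Sequence[LDBlockSpec] = (),
    seed: int = 0,
    variants: Optional[Sequence[VariantKey]] = None,
) -> tuple:
    """Draw a phased multi-population cohort; returns (matrix, ground truth).

    Independent sites are two Bernoulli(af) draws per individual. Within an
    LD block, each haplotype is drawn as a chain: the first member is
    Bernoulli(af); member ``j`` is drawn conditional on member ``j-1`` with
    P(1|1) and P(1|0) chosen so the pair correlation equals ``target_r``.
    Requests beyond the Frechet-feasible bound raise rather than clamp.
    """
    if not specs:
        raise ParameterError("at least one population spec is required")
    m = len(specs[0].af_vector)
    for s in specs:
        if len(s.af_vector) != m:
            raise ParameterError("all populations must share one variant panel")
    if variants is None:
        variants = default_variant_panel(m)
    elif len(variants) != m:
        raise ParameterError("variant panel length differs from af_vector length")

    in_block = set()
    for b in blocks:
        for j in b.member_variants:
            if not 0 <= j < m:
                raise ParameterError(f"block member index {j} outside the panel")
            if j in in_block:
                raise ParameterError(f"variant index {j} appears in two blocks")
            in_block.add(j)

    # feasibility is per population (bounds depend on the pair's AFs)
    for s in specs:
        for b in blocks:
            for a, c in zip(b.member_variants, b.member_variants[1:]):
                lo, hi = feasible_r_bounds(s.af_vector[a], s.af_vector[c])
                if not lo - 1e-12 <= b.target_r <= hi + 1e-12:
                    raise ParameterError(
                        f"target_r={b.target_r} infeasible for AFs "
                        f"({s.af_vector[a]}, {s.af_vector[c]}) in population "
                        f"{s.name}; feasible range is [{lo:.4f}, {hi:.4f}]"
                    )

    samples: List[str] = []
    populations: List[str] = []
    hap_chunks = []
    truth = GroundTruth()
    for s in specs:
        rng = _substream(seed, f"population:{s.name}")
        n_hap = 2 * s.n_individuals
        haps = (rng.random((n_hap, m)) < s.af_vector[None, :]).astype(np.int8)
        for b in blocks:
            _fill_block(haps, s.af_vector, b, rng)
        hap_chunks.append(haps)
        samples.extend(f"{s.name}_{i:05d}" for i in range(s.n_individuals))
        populations.extend([s.name] * s.n_individuals)
        truth.true_af[s.name] = {
            v.vid: float(af) for v, af in zip(variants, s.af_vector)
        }

    haps = np.concatenate(hap_chunks, axis=0)
    n = len(samples)
    alleles = np.stack([haps[0::2], haps[1::2]], axis=2)  # pair consecutive haplotypes
    phased = np.ones((n, m), dtype=bool)
    g = GenotypeMatrix(samples, populations, variants, alleles, phased)
    return g, truth


def _fill_block(haps: np.ndarray, af: np.ndarray, block: LDBlockSpec, rng: np.random.Generator) -> None:
    """Redraw a block's columns as a first-order chain hitting target_r."""
    members = block.member_variants
    r = block.target_r
    n_hap = haps.shape[0]
    first = members[0]
    haps[:, first] = (rng.random(n_hap) < af[first]).astype(np.int8)
    for a, c in zip(members, members[1:]):
        p1, p2 = af[a], af[c]
        q1 = 1 - p1
        denom = np.sqrt(p1 * q1 * p2 * (1 - p2))
        p11 = p1 * p2 + r * denom  # P(X_a=1, X_c=1) on a haplotype
        cond1 = p11 / p1 if p1 > 0 else p2  # P(X_c=1 | X_a=1)
        cond0 = (p2 - p11) / q1 if q1 > 0 else p2
        u = rng.random(n_hap)
        prev = haps[:, a]
        haps[:, c] = np.where(prev == 1, u < cond1, u < cond0).astype(np.int8)


# ---------------------------------------------------------------------------
# Annotation / drug-gene / verdict suite
# ---------------------------------------------------------------------------

def simulate_annotation_suite(
    n_drugs: int,
    n_variants: int,
    direction_mix: float = 0.5,
    seed: int = 0,
    variants: Optional[Sequence[VariantKey]] = None,
    n_tools: int = 3,
    agreement: float = 1.0,
    deleterious_fraction: float = 0.5,
) -> tuple:
    """Generate matched annotation, drug-gene and verdict tables.

    Each variant is assigned one drug (round-robin over ``n_drugs`` synthetic
    drugs spread across the NIAD classes), a direction (negative with
    probability ``direction_mix``), an evidence level in {3, 4} (no level-1/2
    NIAD annotation exists in the curated sources this emulates), and a gene.
    Per-tool verdicts match the variant's true deleteriousness with
    probability ``agreement`` per tool, else are flipped.

    Returns ``(annotations, drug_gene_map, verdict_table, ground_truth)``.
    """
    if not 0.0 <= direction_mix <= 1.0:
        raise ParameterError("direction_mix must lie in [0, 1]")
    if not 0.0 <= agreement <= 1.0:
        raise ParameterError("agreement must lie in [0, 1]")
    if variants is None:
        variants = default_variant_panel(n_variants)
    if n_variants > len(variants):
        raise ParameterError("n_variants exceeds the panel size")
    variants = list(variants)[:n_variants]

    rng = _substream(seed, "annotation_suite")
    drugs = [f"drug{d:03d}" for d in range(n_drugs)]
    classes = {d: NIAD_CLASSES[i % len(NIAD_CLASSES)] for i, d in enumerate(drugs)}
    roles = ("enzyme", "transporter", "target")

    truth = GroundTruth()
    annotations = []
    dg_entries = set()
    verdict_rows = []
    tools = [f"tool{t + 1}" for t in range(n_tools)]
    for j, v in enumerate(variants):
        drug = drugs[j % n_drugs]
        gene = f"GENE{j:03d}"
        role = roles[j % len(roles)]
        negative = bool(rng.random() < direction_mix)
        direction = "negative" if negative else "positive"
        phenotype = "decreased response" if negative else "increased response"
        level = 3 if rng.random() < 0.8 else 4
        annotations.append(
            ClinicalAnnotation(
                variant=v,
                effect_allele=v.alt,
                drugs=(drug,),
                drug_class=classes[drug],
                phenotype_terms=(phenotype,),
                evidence_level=level,
                gene=gene,
            )
        )
        dg_entries.add((drug, gene, role))
        truth.direction[v.vid] = direction

        deleterious = bool(rng.random() < deleterious_fraction)
        if deleterious:
            truth.deleterious.append(v.vid)
        truth.gene_disrupted[gene] = deleterious
        verdicts = []
        for _ in tools:
            correct = rng.random() < agreement
            is_del = deleterious if correct else not deleterious
            verdicts.append("deleterious" if is_del else "tolerated")
        verdict_rows.append(VerdictRow(variant=v, verdicts=tuple(verdicts), gene=gene))

    dmap = DrugGeneMap(dg_entries, classes)
    vtable = VerdictTable(tools, verdict_rows)
    return annotations, dmap, vtable, truth


# ---------------------------------------------------------------------------
# Table serialization (the CLI's simulate output)
# ---------------------------------------------------------------------------

def annotations_to_tsv(annotations: Sequence[ClinicalAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("variant\teffect_allele\tdrugs\tdrug_class\tphenotype\tevidence_level\tgene\n")
        for a in annotations:
            vid = a.variant.vid if isinstance(a.variant, VariantKey) else str(a.variant)
            fh.write(
                "\t".join(
                    [
                        vid,
                        a.effect_allele,
                        ";".join(a.drugs),
                        a.drug_class,
                        ";".join(a.phenotype_terms),
                        str(a.evidence_level),
                        a.gene or "",
                    ]
                )
                + "\n"
            )


def drug_gene_to_tsv(dmap: DrugGeneMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("drug\tgene\trole\tcategory\n")
        for drug, gene, role in sorted(dmap.entries):
            fh.write(f"{drug}\t{gene}\t{role}\t{dmap.categories[drug]}\n")


def verdicts_to_tsv(vtable: VerdictTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\t" + "\t".join(vtable.tools) + "\n")
        for row in vtable:
            v = row.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{row.gene or ''}\t"
                + "\t".join(row.verdicts)
                + "\n"
            )
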