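"""Readers and writers for the external formats.

VCF genotypes are read through cyvcf2 (htslib); all tabular inputs are
tab-separated files with a required header and ``#`` comment lines.
Multi-allelic VCF records are split into biallelic variants; each split
record keeps the original position and its rsID gains an allele suffix,
because every downstream analysis is per effect-allele.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    MISSING,
    ClinicalAnnotation,
    DrugGeneMap,
    FormatError,
    GenotypeMatrix,
    InhibitionRecord,
    ParameterError,
    SchemaError,
    StarAlleleDefinition,
    VariantKey,
    VerdictRow,
    VerdictTable,
    _ALLELE_RE,
)

log = logging.getLogger(__name__)

#: default phenotype-string normalization; extensible via ``extra_phenotype_map``
PHENOTYPE_NORMALIZATION = {
    "increased response": "increased response",
    "decreased response": "decreased response",
    "increased toxicity": "increased toxicity",
    "decreased toxicity": "decreased toxicity",
    "improved response": "increased response",
    "reduced response": "decreased response",
    "increased efficacy": "increased response",
    "decreased efficacy": "decreased response",
    "other": "other",
    # dosage / PK phenotypes have drug-dependent clinical sign: kept as "other"
    "decreased clearance": "other",
    "increased clearance": "other",
    "decreased metabolism": "other",
    "increased metabolism": "other",
    "decreased dose": "other",
    "increased dose": "other",
}

_TSV_KW = dict(sep="\t", comment="#", dtype=str, skip_blank_lines=True)

TABLE_SCHEMAS = {
    "drug_gene": ["drug", "gene", "role", "category"],
    "verdicts": ["chrom", "pos", "ref", "alt"],  # + >=1 tool column
    "inhibitors": ["drug", "enzyme", "strength"],
    "pathways": ["drug", "enzyme", "contribution_fraction"],
    "star_defs": ["gene", "star_name", "chrom", "pos", "ref", "alt", "required_allele"],
}


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise SchemaError(f"{what} table is missing required columns: {absent}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotype_vcf(
    path: str,
    sample_population_map: Optional[Union[str, Mapping[str, str], pd.DataFrame]] = None,
) -> GenotypeMatrix:
    """Read a multi-sample diploid VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are split into biallelic variants: for the k-th
    alternate allele, per-haplotype allele index becomes 1 where the call
    equals k, 0 for any other non-missing allele, preserving the total
    alternate dosage across the split records. Symbolic or non-ACGT
    alternates are skipped with a warning. Input variant order is preserved.
    """
    pop_of = _population_lookup(sample_population_map)
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF contains no samples")

    variants: list = []
    columns: list = []
    phase_cols: list = []
    for rec in vcf:
        if "GT" not in (rec.FORMAT or []):
            raise FormatError(
                f"{path}: record {rec.CHROM}:{rec.POS} lacks the GT FORMAT field"
            )
        gts = rec.genotypes
        calls = np.empty((len(samples), 2), dtype=np.int16)
        phased = np.empty(len(samples), dtype=bool)
        for i, gt in enumerate(gts):
            if len(gt) != 3:
                raise FormatError(
                    f"{path}: non-diploid call for sample {samples[i]} at "
                    f"{rec.CHROM}:{rec.POS}"
                )
            calls[i] = gt[:2]
            phased[i] = bool(gt[2])
        if (calls == MISSING).sum(axis=1).max() == 1:
            raise FormatError(
                f"{path}: half-missing call at {rec.CHROM}:{rec.POS}"
            )
        ref = rec.REF.upper()
        alts = [a.upper() for a in rec.ALT]
        multi = len(alts) > 1
        for k, alt in enumerate(alts, start=1):
            if not _ALLELE_RE.match(alt) or not _ALLELE_RE.match(ref):
                log.warning(
                    "skipping symbolic/non-ACGT allele %s>%s at %s:%d",
                    ref, alt, rec.CHROM, rec.POS,
                )
                continue
            rsid = rec.ID
            if rsid is not None and multi:
                rsid = f"{rsid}_{alt}"
            variants.append(VariantKey(rec.CHROM, rec.POS, ref, alt, rsid=rsid))
            col = np.where(calls == MISSING, MISSING, (calls == k).astype(np.int16))
            columns.append(col.astype(np.int8))
            phase_cols.append(phased.copy())

    n, m = len(samples), len(variants)
    alleles = (
        np.stack(columns, axis=1) if m else np.empty((n, 0, 2), dtype=np.int8)
    )
    phase = (
        np.stack(phase_cols, axis=1) if m else np.empty((n, 0), dtype=bool)
    )
    populations = [pop_of(s) for s in samples]
    return GenotypeMatrix(samples, populations, variants, alleles, phase)


def _population_lookup(spm) -> callable:
    if spm is None:
        return lambda s: "all"
    if isinstance(spm, str):
        df = pd.read_csv(spm, **_TSV_KW)
        _require_columns(df, ["sample", "population"], "sample-population")
        spm = dict(zip(df["sample"], df["population"]))
    elif isinstance(spm, pd.DataFrame):
        _require_columns(spm, ["sample", "population"], "sample-population")
        spm = dict(zip(spm["sample"], spm["population"]))
    mapping = dict(spm)

    def lookup(sample: str) -> str:
        try:
            return mapping[sample]
        except KeyError:
            raise FormatError(f"sample {sample!r} absent from population map") from None

    return lookup


def write_genotype_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF v4.2 file."""
    contigs = []
    for v in g.variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pgxburden\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, v in enumerate(g.variants):
            fields = [
                v.chrom,
                str(v.pos),
                v.rsid or ".",
                v.ref,
                v.alt,
                ".",
                ".",
                ".",
                "GT",
            ]
            for i in range(g.n_samples):
                a, b = g.alleles[i, j]
                sep = "|" if g.phased[i, j] else "/"
                gt = (
                    "." + sep + "."
                    if a == MISSING
                    else f"{a}{sep}{b}"
                )
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def write_population_map(g: GenotypeMatrix, path: str) -> None:
    pd.DataFrame({"sample": g.samples, "population": g.populations}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Clinical annotations
# ---------------------------------------------------------------------------

def _parse_variant_field(text: str):
    """``chrom:pos:ref:alt`` becomes a VariantKey; anything else stays a name."""
    if text.count(":") == 3:
        return VariantKey.from_vid(text)
    return text


def normalize_phenotype(term: str, extra: Optional[Mapping[str, str]] = None):
    key = term.strip().lower()
    table = dict(PHENOTYPE_NORMALIZATION)
    if extra:
        table.update({k.strip().lower(): v for k, v in extra.items()})
    return table.get(key)


def read_clinical_annotations(
    path: str,
    extra_phenotype_map: Optional[Mapping[str, str]] = None,
) -> list:
    """Read a clinical-annotation TSV into :class:`ClinicalAnnotation` records.

    Multi-valued ``drugs``/``phenotype`` cells are split on ``;`` or ``,``.
    Unknown phenotype strings are mapped to ``other`` with a row-level
    warning; rows without an effect allele are rejected with a logged reason.
    """
    df = pd.read_csv(path, **_TSV_KW)
    _require_columns(
        df,
        ["variant", "effect_allele", "drugs", "drug_class", "phenotype", "evidence_level"],
        "clinical annotation",
    )
    records = []
    for idx, row in df.iterrows():
        effect = row["effect_allele"]
        if pd.isna(effect) or not str(effect).strip():
            log.warning("row %d rejected: missing effect allele", idx)
            continue
        terms = []
        for raw in _split_cell(row["phenotype"]):
            norm = normalize_phenotype(raw, extra_phenotype_map)
            if norm is None:
                log.warning(
                    "row %d: unknown phenotype term %r mapped to 'other'", idx, raw
                )
                norm = "other"
            terms.append(norm)
        gene = row.get("gene")
        records.append(
            ClinicalAnnotation(
                variant=_parse_variant_field(str(row["variant"]).strip()),
                effect_allele=str(effect).strip().upper(),
                drugs=tuple(_split_cell(row["drugs"])),
                drug_class=str(row["drug_class"]).strip(),
                phenotype_terms=tuple(terms),
                evidence_level=int(row["evidence_level"]),
                gene=None if pd.isna(gene) else str(gene).strip(),
            )
        )
    return records


def _split_cell(cell) -> list:
    if pd.isna(cell):
        return []
    text = str(cell).replace(";", ",")
    return [p.strip() for p in text.split(",") if p.strip()]


# ---------------------------------------------------------------------------
# Generic schema'd tables
# ---------------------------------------------------------------------------

def read_tables(path: str, schema: str):
    """Read one of the named TSV schemas into its table object.

    ``schema`` is one of ``drug_gene``, ``verdicts``, ``inhibitors``,
    ``pathways`` or ``star_defs``. Unknown columns are preserved by pandas
    but ignored by the package.
    """
    if schema not in TABLE_SCHEMAS:
        raise ParameterError(f"unknown table schema {schema!r}")
    df = pd.read_csv(path, **_TSV_KW)
    _require_columns(df, TABLE_SCHEMAS[schema], schema)
    if schema == "drug_gene":
        return _build_drug_gene(df)
    if schema == "verdicts":
        return _build_verdicts(df)
    if schema == "inhibitors":
        return [
            InhibitionRecord(
                drug=r["drug"],
                enzyme=r["enzyme"],
                strength=r["strength"],
                action=r.get("action", "inhibit") if "action" in df.columns and pd.notna(r.get("action")) else "inhibit",
            )
            for _, r in df.iterrows()
        ]
    if schema == "pathways":
        out = {}
        for _, r in df.iterrows():
            out.setdefault(r["drug"], {})[r["enzyme"]] = float(r["contribution_fraction"])
        return out
    if schema == "star_defs":
        return _build_star_defs(df)


def _build_drug_gene(df: pd.DataFrame) -> DrugGeneMap:
    triples = list(zip(df["drug"], df["gene"], df["role"]))
    if len(triples) != len(set(triples)):
        log.warning("drug_gene table contains duplicate (drug, gene, role) rows; deduplicated")
    categories = {}
    for _, r in df.iterrows():
        prev = categories.get(r["drug"])
        if prev is not None and prev != r["category"]:
            raise SchemaError(
                f"drug {r['drug']!r} listed under two categories ({prev}, {r['category']})"
            )
        categories[r["drug"]] = r["category"]
    return DrugGeneMap(set(triples), categories)


_VERDICT_ALIASES = {
    "d": "deleterious",
    "deleterious": "deleterious",
    "t": "tolerated",
    "tolerated": "tolerated",
    ".": "missing",
    "": "missing",
    "na": "missing",
    "missing": "missing",
}


def _build_verdicts(df: pd.DataFrame) -> VerdictTable:
    fixed = set(TABLE_SCHEMAS["verdicts"]) | {"gene"}
    tools = [c for c in df.columns if c not in fixed]
    if not tools:
        raise SchemaError("verdicts table has no tool columns")
    rows = []
    for _, r in df.iterrows():
        verdicts = []
        for t in tools:
            raw = "" if pd.isna(r[t]) else str(r[t]).strip().lower()
            if raw not in _VERDICT_ALIASES:
                raise SchemaError(f"unrecognized verdict value {r[t]!r} in column {t}")
            verdicts.append(_VERDICT_ALIASES[raw])
        gene = r.get("gene")
        rows.append(
            VerdictRow(
                variant=VariantKey(
                    str(r["chrom"]), int(r["pos"]), r["ref"].upper(), r["alt"].upper()
                ),
                verdicts=tuple(verdicts),
                gene=None if gene is None or pd.isna(gene) else str(gene),
            )
        )
    return VerdictTable(tools, rows)


def _build_star_defs(df: pd.DataFrame) -> list:
    defs = []
    for (gene, star), grp in df.groupby(["gene", "star_name"], sort=False):
        alleles = tuple(
            (
                VariantKey(str(r["chrom"]), int(r["pos"]), r["ref"].upper(), r["alt"].upper()),
                str(r["required_allele"]).upper(),
            )
            for _, r in grp.iterrows()
        )
        defs.append(StarAlleleDefinition(gene=gene, star_name=star, defining_alleles=alleles))
    return defs


def match_effect_allele(key: VariantKey, effect_allele: str) -> Optional[int]:
    """Map an annotation's effect allele onto a variant's ref/alt index.

    Returns 0 or 1, or ``None`` when the allele matches neither (the row is
    then rejected by the caller; strand flips are never auto-resolved).
    """
    allele = effect_allele.strip().upper()
    if allele == key.alt:
        return 1
    if allele == key.ref:
        return 0
    return None
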