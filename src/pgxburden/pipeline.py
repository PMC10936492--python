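"""End-to-end orchestration: one config, deterministic staged outputs, manifest.

Stage order: inputs (read or simulate) -> direction classification ->
population frequency comparison -> LD pruning -> burden profiles and
cross-population tests -> deleteriousness consensus and common-variant
filter -> drug-function disruption -> gene sharing / DDI / DDGI analysis.
Every stage writes its tables before the next stage runs, so partial output
of a failed run is inspectable; the manifest records row counts per table
and marks incomplete runs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .burden import burden_profile, compare_burden, comparisons_to_frame
from .classify import (
    DeleteriousCall,
    classify_directions,
    consensus_deleterious,
    filter_common_deleterious,
)
from .disruption import (
    disruption_report,
    gene_disruption,
    reports_to_frame,
    sankey_table,
)
from .frequency import allele_frequency, compare_population_frequencies
from .interactions import (
    build_network,
    classify_ddgi,
    inhibitor_join,
    network_edge_list,
    network_to_json,
    overlap_analysis,
)
from .io_formats import (
    match_effect_allele,
    read_clinical_annotations,
    read_genotype_vcf,
    read_tables,
    write_genotype_vcf,
    write_population_map,
)
from .ld import prune_with_reasons
from .model import ParameterError, UndefinedFrequencyError, VariantKey
from .synthetic import (
    LDBlockSpec,
    PopulationSpec,
    annotations_to_tsv,
    drug_gene_to_tsv,
    simulate_annotation_suite,
    simulate_cohort,
    verdicts_to_tsv,
)

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "r2": 0.2,
    "af_common": 0.01,
    "min_tools": 2,
    "alpha": 0.05,
    "af_min_disruption": 0.01,
    "major_threshold": 0.5,
}


@dataclass
class PipelineConfig:
    inputs: Optional[dict] = None       # paths: vcf, populations, annotations, ...
    simulate: Optional[dict] = None     # populations/blocks/annotation_suite specs
    thresholds: dict = field(default_factory=dict)
    reference_population: Optional[str] = None
    seed: int = 0
    out_dir: str = "pgxburden_out"
    efficacy_only: bool = False
    gene_af_mode: str = "max"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ParameterError(
                "exactly one of 'inputs' and 'simulate' must be present"
            )
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        for name in ("r2", "af_common", "alpha", "af_min_disruption", "major_threshold"):
            val = self.thresholds[name]
            if not 0 < val <= 1:
                raise ParameterError(f"threshold {name}={val} outside (0, 1]")
        if self.thresholds["min_tools"] < 1:
            raise ParameterError("min_tools must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _simulate_inputs(cfg: PipelineConfig, out: Path) -> dict:
    sim = cfg.simulate
    specs = [
        PopulationSpec(p["name"], int(p["n_individuals"]), p["af_vector"])
        for p in sim["populations"]
    ]
    blocks = [
        LDBlockSpec(b["member_variants"], float(b["target_r"]))
        for b in sim.get("blocks", [])
    ]
    g, truth = simulate_cohort(specs, blocks, seed=cfg.seed)
    suite = sim.get("annotation_suite", {})
    annotations, dmap, verdicts, suite_truth = simulate_annotation_suite(
        n_drugs=int(suite.get("n_drugs", 8)),
        n_variants=int(suite.get("n_variants", len(g.variants))),
        direction_mix=float(suite.get("direction_mix", 0.5)),
        seed=cfg.seed,
        variants=g.variants,
        n_tools=int(suite.get("n_tools", 3)),
        agreement=float(suite.get("agreement", 1.0)),
        deleterious_fraction=float(suite.get("deleterious_fraction", 0.5)),
    )
    truth.direction = suite_truth.direction
    truth.deleterious = suite_truth.deleterious
    truth.gene_disrupted = suite_truth.gene_disrupted
    write_genotype_vcf(g, str(out / "cohort.vcf"))
    write_population_map(g, str(out / "populations.tsv"))
    annotations_to_tsv(annotations, str(out / "annotations.tsv"))
    drug_gene_to_tsv(dmap, str(out / "drug_gene.tsv"))
    verdicts_to_tsv(verdicts, str(out / "verdicts.tsv"))
    truth.to_json(str(out / "ground_truth.json"))
    return {
        "genotypes": g,
        "annotations": annotations,
        "drug_gene": dmap,
        "verdicts": verdicts,
        "star_defs": None,
        "inhibitors": None,
        "pathways": None,
    }


def _read_inputs(cfg: PipelineConfig) -> dict:
    paths = cfg.inputs
    data = {
        "genotypes": read_genotype_vcf(paths["vcf"], paths.get("populations")),
        "annotations": read_clinical_annotations(paths["annotations"]),
        "drug_gene": read_tables(paths["drug_gene"], "drug_gene"),
        "verdicts": read_tables(paths["verdicts"], "verdicts")
        if paths.get("verdicts")
        else None,
        "star_defs": read_tables(paths["star_defs"], "star_defs")
        if paths.get("star_defs")
        else None,
        "inhibitors": read_tables(paths["inhibitors"], "inhibitors")
        if paths.get("inhibitors")
        else None,
        "pathways": read_tables(paths["pathways"], "pathways")
        if paths.get("pathways")
        else None,
    }
    return data


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to the out dir)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = cfg.thresholds
    manifest = {
        "software": f"pgxburden {__version__}",
        "seed": cfg.seed,
        "config": {
            "thresholds": thresholds,
            "reference_population": cfg.reference_population,
            "simulate": cfg.simulate,
            "inputs": cfg.inputs,
        },
        "stages": {},
        "tables": {},
        "complete": False,
    }
    log.info("thresholds: %s", thresholds)
    t0 = time.perf_counter()
    stage = "inputs"
    try:
        data = _simulate_inputs(cfg, out) if cfg.simulate else _read_inputs(cfg)
        g = data["genotypes"]
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        reference = cfg.reference_population or g.populations[0]
        populations = sorted(set(g.populations))

        # --- direction classification -----------------------------------
        stage = "classify"
        t = time.perf_counter()
        directional = classify_directions(data["annotations"], cfg.efficacy_only)
        rows = []
        for d in directional:
            vid = (
                d.base.variant.vid
                if isinstance(d.base.variant, VariantKey)
                else str(d.base.variant)
            )
            rows.append(
                {
                    "variant": vid,
                    "effect_allele": d.base.effect_allele,
                    "drugs": ";".join(d.base.drugs),
                    "drug_class": d.base.drug_class,
                    "phenotype": ";".join(d.base.phenotype_terms),
                    "evidence_level": d.base.evidence_level,
                    "gene": d.base.gene or "",
                    "direction": d.direction,
                    "rationale": d.rationale,
                }
            )
        _emit(pd.DataFrame(rows), out / "directional_annotations.tsv", manifest)
        manifest["stages"][stage] = round(time.perf_counter() - t, 3)

        # --- population frequency comparison ----------------------------
        stage = "frequency"
        t = time.perf_counter()
        panel = [
            (d.base.variant, d.base.effect_allele)
            for d in directional
            if isinstance(d.base.variant, VariantKey)
            and d.base.variant.vid in g._index
        ]
        freq_rows = []
        for v, allele in panel:
            for pop in populations:
                try:
                    fr = allele_frequency(g, v, allele, pop)
                except UndefinedFrequencyError:
                    continue
                freq_rows.append(
                    {
                        "variant": v.vid,
                        "rsid": v.rsid or "",
                        "population": pop,
                        "effect_allele": fr.effect_allele,
                        "af": fr.af,
                        "n_chromosomes": fr.n_chromosomes,
                    }
                )
        _emit(pd.DataFrame(freq_rows), out / "allele_frequencies.tsv", manifest)
        if len(populations) > 1 and panel:
            comparisons = compare_population_frequencies(
                g, panel, reference, alpha=thresholds["alpha"]
            )
            comp_rows = [
                {
                    "variant": c.variant.vid,
                    "population_a": c.population_a,
                    "population_b": c.population_b,
                    "odds_ratio": c.odds_ratio,
                    "p_value": c.p_value,
                    "q_value": c.q_value,
                    "significant": c.significant,
                }
                for c in comparisons
            ]
            _emit(pd.DataFrame(comp_rows), out / "frequency_comparisons.tsv", manifest)
        manifest["stages"][stage] = round(time.perf_counter() - t, 3)

        # --- LD pruning --------------------------------------------------
        stage = "prune"
        t = time.perf_counter()
        panel_variants = [v for v, _ in panel]
        kept, dropped = prune_with_reasons(g, panel_variants, thresholds["r2"])
        kept_ids = {v.vid for v in kept}
        _emit(
            pd.DataFrame({"variant": [v.vid for v in kept]}),
            out / "pruned_keep.tsv",
            manifest,
        )
        _emit(
            pd.DataFrame(
                [
                    {"variant": v.vid, "partner": p.vid, "r_squared": r2}
                    for v, p, r2 in dropped
                ],
                columns=["variant", "partner", "r_squared"],
            ),
            out / "pruned_drop.tsv",
            manifest,
        )
        manifest["stages"][stage] = round(time.perf_counter() - t, 3)

        # --- burden ------------------------------------------------------
        stage = "burden"
        t = time.perf_counter()
        burden_panel = [
            d
            for d in directional
            if d.direction in ("positive", "negative")
            and isinstance(d.base.variant, VariantKey)
            and d.base.variant.vid in kept_ids
        ]
        profiles = burden_profile(g, burden_panel)
        _emit(profiles, out / "burden_profiles.tsv", manifest)
        if len(populations) > 1 and not profiles.empty:
            burden_comp = compare_burden(profiles, reference)
            _emit(
                comparisons_to_frame(burden_comp),
                out / "burden_comparisons.tsv",
                manifest,
            )
        manifest["stages"][stage] = round(time.perf_counter() - t, 3)

        # --- deleteriousness consensus + common filter -------------------
        stage = "deleterious"
        t = time.perf_counter()
        disruptions = []
        if data["verdicts"] is not None:
            calls = []
            for row in data["verdicts"]:
                try:
                    consensus = consensus_deleterious(row, thresholds["min_tools"])
                except Exception:
                    continue
                try:
                    af = (
                        allele_frequency(g, row.variant, row.variant.alt, reference).af
                        if row.variant.vid in g._index
                        else 0.0
                    )
                except UndefinedFrequencyError:
                    af = 0.0
                n_del = sum(v == "deleterious" for v in row.verdicts)
                calls.append(
                    DeleteriousCall(
                        variant=row.variant,
                        n_tools_deleterious=n_del,
                        consensus=consensus,
                        effect_af=af,
                        common=af > thresholds["af_common"],
                        gene=row.gene,
                    )
                )
            common = filter_common_deleterious(calls, thresholds["af_common"])
            _emit(
                pd.DataFrame(
                    [
                        {
                            "variant": c.variant.vid,
                            "gene": c.gene or "",
                            "n_tools_deleterious": c.n_tools_deleterious,
                            "consensus": c.consensus,
                            "effect_af": c.effect_af,
                            "common": c.common,
                        }
                        for c in calls
                    ],
                    columns=[
                        "variant", "gene", "n_tools_deleterious",
                        "consensus", "effect_af", "common",
                    ],
                ),
                out / "deleterious_calls.tsv",
                manifest,
            )
            labelled = [c for c in common if c.gene]
            disruptions = gene_disruption(labelled, mode=cfg.gene_af_mode)
        manifest["stages"][stage] = round(time.perf_counter() - t, 3)

        # --- disruption ---------------------------------------------------
        stage = "disruption"
        t = time.perf_counter()
        reports = disruption_report(
            data["drug_gene"], disruptions, thresholds["af_min_disruption"]
        )
        _emit(reports_to_frame(reports), out / "disruption_report.tsv", manifest)
        flows = sankey_table(reports, data["drug_gene"], disruptions)
        flows = flows.rename(columns={"drug": "source", "gene": "target"})
        _emit(flows, out / "sankey_flows.tsv", manifest)
        manifest["stages"][stage] = round(time.perf_counter() - t, 3)

        # --- interactions -------------------------------------------------
        stage = "interactions"
        t = time.perf_counter()
        dmap = data["drug_gene"]
        categories = set(dmap.categories.values())
        if len(categories) > 1:
            niad_cat = cfg.inputs.get("niad_category") if cfg.inputs else None
            niad_cat = niad_cat or sorted(categories)[0]
            overlaps = overlap_analysis(dmap, niad_cat)
            _emit(
                pd.DataFrame(
                    [
                        {
                            "category": o.category,
                            "n_genes": o.n_genes,
                            "n_shared_with_niads": o.n_shared_with_niads,
                            "overlap_fraction": o.overlap_fraction,
                            "intersection_all_categories": ";".join(
                                sorted(o.intersection_all_categories)
                            ),
                        }
                        for o in overlaps
                    ],
                    columns=[
                        "category", "n_genes", "n_shared_with_niads",
                        "overlap_fraction", "intersection_all_categories",
                    ],
                ),
                out / "overlap_summary.tsv",
                manifest,
            )
        net = build_network(dmap)
        with open(out / "network.json", "w") as fh:
            json.dump(network_to_json(net), fh, indent=1, sort_keys=True)
        _emit(network_edge_list(net), out / "network_edges.tsv", manifest)
        if data["inhibitors"]:
            ddi = inhibitor_join(dmap, data["inhibitors"])
            _emit(ddi, out / "ddi_predictions.tsv", manifest)
            if data["pathways"]:
                ddgi_rows = []
                for victim, pathways in sorted(data["pathways"].items()):
                    for rec in data["inhibitors"]:
                        for gene in sorted(pathways):
                            for pclass in ("PM", "UM"):
                                pred = classify_ddgi(
                                    victim,
                                    rec.drug,
                                    pathways,
                                    data["inhibitors"],
                                    (gene, pclass),
                                    thresholds["major_threshold"],
                                )
                                if pred.category != "none":
                                    ddgi_rows.append(
                                        {
                                            "victim": pred.victim,
                                            "perpetrator": pred.perpetrator,
                                            "gene": pred.gene,
                                            "phenotype": pred.phenotype,
                                            "category": pred.category,
                                            "rationale": pred.rationale,
                                        }
                                    )
                ddgi = pd.DataFrame(
                    ddgi_rows,
                    columns=[
                        "victim", "perpetrator", "gene",
                        "phenotype", "category", "rationale",
                    ],
                ).drop_duplicates()
                _emit(ddgi, out / "ddgi_predictions.tsv", manifest)
        manifest["stages"][stage] = round(time.perf_counter() - t, 3)
        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(manifest, out)
        raise
    _write_manifest(manifest, out)
    return manifest


def _emit(df: pd.DataFrame, path: Path, manifest: dict, float_fmt: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_fmt)
    manifest["tables"][path.name] = int(len(df))


def _write_manifest(manifest: dict, out: Path) -> None:
    tmp = out / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    tmp.replace(out / "manifest.json")
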