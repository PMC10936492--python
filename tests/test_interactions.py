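"""Gene sharing, drug-gene networks, DDI joins and DDGI rule classification."""

import itertools

import pytest

from pgxburden.interactions import (
    build_network,
    classify_ddgi,
    inhibitor_join,
    network_to_json,
    overlap_analysis,
)
from pgxburden.model import DrugGeneMap, InhibitionRecord, ParameterError


def dmap_from(entries, categories):
    return DrugGeneMap(entries, categories)


class TestOverlapAnalysis:
    def _map(self, niad_genes, other_genes):
        entries = {("niad_drug", g, "enzyme") for g in niad_genes}
        entries |= {("other_drug", g, "enzyme") for g in other_genes}
        return dmap_from(
            entries, {"niad_drug": "niad", "other_drug": "ppi"}
        )

    def test_partial_overlap_fraction(self):
        out = overlap_analysis(self._map({"A", "B", "D"}, {"A", "B", "C"}), "niad")
        (summary,) = out
        assert summary.n_genes == 3
        assert summary.n_shared_with_niads == 2
        assert summary.overlap_fraction == pytest.approx(2 / 3)
        assert summary.intersection_all_categories == {"A", "B"}

    def test_identical_sets(self):
        (summary,) = overlap_analysis(self._map({"A", "B"}, {"A", "B"}), "niad")
        assert summary.overlap_fraction == 1.0
        assert summary.intersection_all_categories == {"A", "B"}

    def test_disjoint_sets(self):
        (summary,) = overlap_analysis(self._map({"A"}, {"B"}), "niad")
        assert summary.overlap_fraction == 0.0
        assert summary.intersection_all_categories == frozenset()

    def test_duplicate_rows_cannot_inflate(self):
        entries = [
            ("niad_drug", "A", "enzyme"),
            ("niad_drug", "A", "enzyme"),
            ("other_drug", "A", "enzyme"),
        ]
        out = overlap_analysis(
            dmap_from(entries, {"niad_drug": "niad", "other_drug": "ppi"}), "niad"
        )
        assert out[0].n_genes == 1 and out[0].overlap_fraction == 1.0


class TestNetwork:
    def _map(self):
        entries = {
            ("pioglitazone", "CYP2C8", "enzyme"),
            ("pioglitazone", "CYP3A4", "enzyme"),
            ("pioglitazone", "SLCO1B1", "transporter"),
            ("pioglitazone", "PPARG", "target"),
            ("gemfibrozil", "CYP2C8", "enzyme"),
            ("gemfibrozil", "SLCO1B1", "transporter"),
            ("verapamil", "CYP3A4", "enzyme"),
        }
        cats = {
            "pioglitazone": "niad",
            "gemfibrozil": "lipid_modifying",
            "verapamil": "antiarrhythmic",
        }
        return dmap_from(entries, cats)

    def test_gene_degree_counts_incident_drugs(self):
        net = build_network(self._map())
        assert net.gene_degree["CYP2C8"] == 2
        assert net.gene_degree["PPARG"] == 1

    def test_handshake_identity(self):
        dmap = self._map()
        net = build_network(dmap)
        assert sum(net.gene_degree.values()) == len({(d, g) for d, g, _ in dmap.entries})

    def test_share_score_fraction_of_cross_category_genes(self):
        net = build_network(self._map())
        # pioglitazone: CYP2C8, CYP3A4, SLCO1B1 shared with other categories;
        # PPARG is not -> 3/4
        assert net.drug_share_score["pioglitazone"] == pytest.approx(0.75)

    def test_single_category_gives_zero_share_scores(self):
        dmap = dmap_from(
            {("metformin", "SLC22A1", "transporter")}, {"metformin": "niad"}
        )
        net = build_network(dmap)
        assert net.drug_share_score["metformin"] == 0.0

    def test_node_link_json_carries_scores(self):
        data = network_to_json(build_network(self._map()))
        nodes = {n["id"]: n for n in data["nodes"]}
        assert nodes["CYP2C8"]["degree"] == 2
        assert "share_score" in nodes["pioglitazone"]


class TestInhibitorJoin:
    def _map(self):
        entries = {
            ("saxagliptin", "CYP3A4", "enzyme"),
            ("saxagliptin", "CYP3A5", "enzyme"),
            ("repaglinide", "CYP2C8", "enzyme"),
            ("repaglinide", "SLCO1B1", "transporter"),
        }
        return dmap_from(
            entries, {"saxagliptin": "niad", "repaglinide": "niad"}
        )

    def test_moderate_inhibitor_of_victim_enzyme(self):
        df = inhibitor_join(
            self._map(), [InhibitionRecord("verapamil", "CYP3A4", "moderate")]
        )
        (row,) = df.itertuples(index=False)
        assert (row.victim, row.perpetrator, row.strength) == (
            "saxagliptin", "verapamil", "moderate",
        )

    def test_strong_inhibitor_carried_through(self):
        df = inhibitor_join(
            self._map(), [InhibitionRecord("gemfibrozil", "CYP2C8", "strong")]
        )
        assert df.iloc[0].victim == "repaglinide"
        assert df.iloc[0].strength == "strong"

    def test_no_shared_enzyme_no_row_and_transporters_do_not_match(self):
        df = inhibitor_join(
            self._map(),
            [
                InhibitionRecord("omeprazole", "CYP2C19", "moderate"),
                InhibitionRecord("x", "SLCO1B1", "weak"),  # transporter role
            ],
        )
        assert df.empty

    def test_self_pairs_excluded_and_monotone_in_records(self):
        recs = [InhibitionRecord("saxagliptin", "CYP3A4", "weak")]
        assert inhibitor_join(self._map(), recs).empty
        base = inhibitor_join(
            self._map(), [InhibitionRecord("verapamil", "CYP3A4", "moderate")]
        )
        more = inhibitor_join(
            self._map(),
            [
                InhibitionRecord("verapamil", "CYP3A4", "moderate"),
                InhibitionRecord("gemfibrozil", "CYP2C8", "strong"),
            ],
        )
        assert len(more) > len(base)
        pairs = set(map(tuple, base[["victim", "perpetrator"]].to_numpy()))
        assert pairs <= set(map(tuple, more[["victim", "perpetrator"]].to_numpy()))


ACTION_SIGN = {"inhibit": -1, "induce": +1, "none": 0}
PHENO_SIGN = {"PM": -1, "NM": 0, "UM": +1}


def ddgi_rule_oracle(pathways, actions, gene, pclass):
    """Independent lookup-table statement of the category definitions."""
    sign = PHENO_SIGN[pclass]
    if gene not in pathways or sign == 0:
        return "none"
    act = ACTION_SIGN[actions.get(gene, "none")]
    if act == sign:
        return 1  # same pathway pushed the same way: magnified
    if act == -sign and act != 0:
        return 3  # same pathway pushed opposite ways: opposing
    if any(
        ACTION_SIGN[a] == sign
        for e, a in actions.items()
        if e != gene and e in pathways
    ):
        return 2  # a different pathway of the same victim pushed the same way
    return "none"


class TestClassifyDdgi:
    def test_pm_plus_inhibitor_on_minor_shared_pathway_is_category_1(self):
        # a sulfonylurea with a major CYP3A4 and minor CYP2C19 pathway,
        # co-administered with a CYP2C19 inhibitor in a CYP2C19 poor metabolizer
        pred = classify_ddgi(
            "glyburide",
            "omeprazole",
            {"CYP3A4": 0.6, "CYP2C19": 0.3},
            [InhibitionRecord("omeprazole", "CYP2C19", "moderate")],
            ("CYP2C19", "PM"),
        )
        assert pred.category == 1
        assert "CYP2C19" in pred.rationale

    def test_phenotype_gene_outside_pathway_set_is_none(self):
        pred = classify_ddgi(
            "saxagliptin",
            "fluvoxamine",
            {"CYP3A4": 0.7, "CYP3A5": 0.2},
            [InhibitionRecord("fluvoxamine", "CYP3A4", "strong")],
            ("CYP2C19", "PM"),
        )
        assert pred.category == "none"

    def test_different_pathway_magnification_is_category_2(self):
        pred = classify_ddgi(
            "victim",
            "perp",
            {"CYP3A4": 0.5, "CYP2C19": 0.3},
            [InhibitionRecord("perp", "CYP3A4", "moderate")],
            ("CYP2C19", "PM"),
        )
        assert pred.category == 2

    def test_um_against_inhibitor_is_category_3(self):
        pred = classify_ddgi(
            "victim",
            "perp",
            {"CYP2C19": 0.8},
            [InhibitionRecord("perp", "CYP2C19", "moderate")],
            ("CYP2C19", "UM"),
        )
        assert pred.category == 3

    def test_contribution_sum_above_one_rejected(self):
        with pytest.raises(ParameterError):
            classify_ddgi("v", "p", {"E1": 0.8, "E2": 0.4}, [], ("E1", "PM"))

    def test_exhaustive_agreement_with_rule_table_oracle(self):
        """All 486 combinations of the 3-enzyme toy grid match the oracle."""
        enzymes = ("E1", "E2", "E3")
        pathway_sets = [
            {"E1": 0.5, "E2": 0.3},  # two-pathway victim, E3 outside
            {"E1": 0.9},             # single-pathway victim
        ]
        checked = 0
        for pathways in pathway_sets:
            for actions in itertools.product(("inhibit", "induce", "none"), repeat=3):
                action_map = dict(zip(enzymes, actions))
                records = [
                    InhibitionRecord("perp", e, "moderate", action=a)
                    for e, a in action_map.items()
                    if a != "none"
                ]
                for gene, pclass in itertools.product(enzymes, ("PM", "NM", "UM")):
                    pred = classify_ddgi(
                        "victim", "perp", pathways, records, (gene, pclass)
                    )
                    expected = ddgi_rule_oracle(pathways, action_map, gene, pclass)
                    assert pred.category == expected, (
                        pathways, action_map, gene, pclass,
                    )
                    if pred.category == 3:
                        # opposing signs are a hard invariant of category 3
                        sign = PHENO_SIGN[pclass]
                        act = ACTION_SIGN[action_map[gene]]
                        assert act == -sign and act != 0
                    checked += 1
        assert checked == 486
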