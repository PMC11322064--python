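"""Overlays, ortholog designation, comparison tables, stats and search."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funcdash.comparison import (
    HitRecord,
    OrthologTable,
    db_stats,
    overlay,
    pathway_comparison,
    reciprocal_orthologs,
    search,
    transporter_comparison,
)
from funcdash.core_model import (
    Gene,
    OrganismBundle,
    Pathway,
    Reaction,
    TransportReaction,
)
from funcdash.subsystems import build_dashboard
from tests.conftest import make_toy_bundle
from tests.test_subsystems import TestBuildDashboard


def brute_force_overlay(sets):
    """Count memberships item by item (independent of the implementation)."""
    orgs = list(sets)
    n = len(orgs)
    common = sum(
        1
        for item in set().union(*sets.values())
        if all(item in sets[o] for o in orgs)
    )
    out = {}
    for o in orgs:
        unique = sum(
            1
            for item in sets[o]
            if not any(item in sets[p] for p in orgs if p != o)
        )
        out[o] = (len(sets[o]), unique, len(sets[o]) - common - unique)
    return common, out


class TestOverlay:
    def test_two_organisms_omit_white_bar(self):
        stats = overlay({"a": {1, 2}, "b": {2, 3}})
        assert stats.white_bar_omitted

    def test_identical_sets_all_common(self):
        s = {1, 2, 3}
        stats = overlay({o: set(s) for o in "abc"})
        assert stats.common_count == 3
        assert all(v == 0 for v in stats.unique.values())
        assert all(v == 0 for v in stats.shared.values())
        assert not stats.white_bar_omitted

    def test_worked_three_organism_example(self):
        stats = overlay({"s1": {"a", "b", "c"}, "s2": {"a", "b"}, "s3": {"a", "d"}})
        assert stats.common_count == 1
        assert stats.unique == {"s1": 1, "s2": 0, "s3": 1}
        assert stats.shared == {"s1": 1, "s2": 1, "s3": 0}

    def test_single_set_is_error(self):
        with pytest.raises(ValueError):
            overlay({"a": {1}})

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.sets(st.integers(0, 30), max_size=20), min_size=2, max_size=10
        )
    )
    def test_partition_identity_on_random_families(self, families):
        sets = {f"o{i}": s for i, s in enumerate(families)}
        stats = overlay(sets)
        common, expected = brute_force_overlay(sets)
        assert stats.common_count == common
        for o in sets:
            total, unique, shared = expected[o]
            assert stats.totals[o] == total
            assert stats.unique[o] == unique
            assert stats.shared[o] == shared
            assert (
                stats.totals[o]
                == stats.common_count + stats.shared[o] + stats.unique[o]
            )
        assert stats.white_bar_omitted == (len(sets) == 2)


class TestReciprocalOrthologs:
    def test_bidirectional_below_threshold_accepted(self):
        hits = [
            HitRecord("A", "a1", "B", "b1", 1e-4),
            HitRecord("B", "b1", "A", "a1", 1e-5),
        ]
        table = reciprocal_orthologs(hits)
        assert table.are_orthologs(("A", "a1"), ("B", "b1"))

    def test_one_directional_rejected(self):
        table = reciprocal_orthologs([HitRecord("A", "a1", "B", "b1", 1e-6)])
        assert len(table) == 0

    def test_reverse_at_threshold_rejected(self):
        hits = [
            HitRecord("A", "a1", "B", "b1", 1e-6),
            HitRecord("B", "b1", "A", "a1", 0.01),
        ]
        assert len(reciprocal_orthologs(hits)) == 0
        # strictly-below semantics: exactly 0.001 is rejected too
        hits[1] = HitRecord("B", "b1", "A", "a1", 0.001)
        assert len(reciprocal_orthologs(hits)) == 0

    def test_minimum_e_value_kept_per_directed_pair(self):
        hits = [
            HitRecord("A", "a1", "B", "b1", 0.5),
            HitRecord("A", "a1", "B", "b1", 1e-8),  # better duplicate
            HitRecord("B", "b1", "A", "a1", 1e-4),
        ]
        assert len(reciprocal_orthologs(hits)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_and_row_order_invariance(self, seed):
        rng = random.Random(seed)
        hits = []
        for _ in range(80):
            a, b = rng.sample(["A", "B", "C"], 2)
            hits.append(
                HitRecord(
                    a,
                    f"{a}{rng.randint(0, 15)}",
                    b,
                    f"{b}{rng.randint(0, 15)}",
                    10 ** rng.uniform(-8, 0),
                )
            )
        t1 = reciprocal_orthologs(hits)
        shuffled = hits[:]
        rng.shuffle(shuffled)
        t2 = reciprocal_orthologs(shuffled)
        assert t1.pairs() == t2.pairs()
        for pair in t1.pairs():
            x, y = tuple(pair)
            assert t1.are_orthologs(x, y) and t1.are_orthologs(y, x)

    def test_raising_threshold_never_removes_pairs(self):
        rng = random.Random(9)
        hits = []
        for _ in range(60):
            a, b = rng.sample(["A", "B"], 2)
            hits.append(
                HitRecord(
                    a,
                    f"{a}{rng.randint(0, 10)}",
                    b,
                    f"{b}{rng.randint(0, 10)}",
                    10 ** rng.uniform(-6, 0),
                )
            )
        for lo, hi in [(1e-4, 1e-3), (1e-3, 1e-2), (1e-2, 1e-1)]:
            assert reciprocal_orthologs(hits, lo).pairs() <= reciprocal_orthologs(
                hits, hi
            ).pairs()


def two_org_pathway_world():
    """orgA has both enzymes of a 2-step pathway; orgB has the pathway but
    no enzyme on step r2, and gene b7 orthologous to orgA's r2 enzyme."""
    a = OrganismBundle(org_id="A")
    b = OrganismBundle(org_id="B")
    a.genes = {"a1": Gene(id="a1"), "a2": Gene(id="a2")}
    b.genes = {"b1": Gene(id="b1"), "b7": Gene(id="b7")}
    for org, enz in ((a, {"r1": ("a1",), "r2": ("a2",)}), (b, {"r1": ("b1",), "r2": ()})):
        org.reactions = {
            "r1": Reaction(
                id="r1",
                reactant_ids=("x",),
                product_ids=("y",),
                enzyme_gene_ids=enz["r1"],
                enzyme_evidence={g: "experimental" for g in enz["r1"]},
            ),
            "r2": Reaction(
                id="r2",
                reactant_ids=("y",),
                product_ids=("z",),
                enzyme_gene_ids=enz["r2"],
                enzyme_evidence={g: "computational" for g in enz["r2"]},
            ),
        }
        org.pathways_present = {
            "PWY": Pathway(
                id="PWY",
                name="toy pathway",
                reaction_ids=("r1", "r2"),
                primary_reactants=("x",),
                primary_products=("z",),
                key_reactions=("r2",),
            )
        }
    orthologs = OrthologTable([(("A", "a2"), ("B", "b7"))])
    return a, b, orthologs


class TestPathwayComparison:
    def test_missing_enzyme_cell_gets_ortholog_suggestion(self):
        a, b, orthologs = two_org_pathway_world()
        table = pathway_comparison([a, b], "PWY", orthologs)
        cell = table.cells[("r2", "B")]
        assert cell.enzymes == []
        assert [(s.gene, s.source_org, s.source_gene) for s in cell.suggestions] == [
            ("b7", "A", "a2")
        ]

    def test_filled_cells_have_no_suggestions(self):
        a, b, orthologs = two_org_pathway_world()
        b.reactions["r2"] = Reaction(
            id="r2", reactant_ids=("y",), product_ids=("z",),
            enzyme_gene_ids=("b7",), enzyme_evidence={"b7": "computational"},
        )
        table = pathway_comparison([a, b], "PWY", orthologs)
        for cell in table.cells.values():
            assert not cell.suggestions

    def test_key_step_without_enzymes_flagged_everywhere(self):
        a, b, orthologs = two_org_pathway_world()
        a.reactions["r2"] = Reaction(id="r2", reactant_ids=("y",), product_ids=("z",))
        table = pathway_comparison([a, b], "PWY", None)
        for org in ("A", "B"):
            assert {"key-step", "no-enzyme"} <= table.statuses[("r2", org)]

    def test_enzyme_identified_status(self):
        a, b, _ = two_org_pathway_world()
        table = pathway_comparison([a, b], "PWY", None)
        assert "enzyme-identified" in table.statuses[("r1", "A")]
        assert "no-enzyme" in table.statuses[("r2", "B")]

    def test_unknown_pathway_is_error(self):
        a, b, _ = two_org_pathway_world()
        with pytest.raises(KeyError, match="NOPE"):
            pathway_comparison([a, b], "NOPE", None)

    def test_suggestions_are_true_orthologs_of_assigned_enzymes(self):
        a, b, orthologs = two_org_pathway_world()
        table = pathway_comparison([a, b], "PWY", orthologs)
        for (rid, org), cell in table.cells.items():
            for s in cell.suggestions:
                assert orthologs.are_orthologs((org, s.gene), (s.source_org, s.source_gene))
                source_cell = table.cells[(rid, s.source_org)]
                assert s.source_gene in [g for g, _ in source_cell.enzymes]


class TestTransporterComparison:
    def test_counts_listed_per_organism(self):
        a = make_toy_bundle("A")
        b = make_toy_bundle("B")
        for i in (2, 3):
            b.genes[f"zt{i}"] = Gene(id=f"zt{i}")
            b.transport_reactions[f"T{i}"] = TransportReaction(
                id=f"T{i}", primary_substrate="arg", transporter_gene_ids=(f"zt{i}",)
            )
        inv = transporter_comparison([a, b], "arg")
        assert len(inv["A"].transporters) == 1
        assert len(inv["B"].transporters) == 3

    def test_no_suggestions_when_all_have_transporters(self):
        a = make_toy_bundle("A")
        b = make_toy_bundle("B")
        orthologs = OrthologTable([(("A", "zt1"), ("B", "zt1"))])
        inv = transporter_comparison([a, b], "arg", orthologs)
        assert not inv["A"].suggestions and not inv["B"].suggestions

    def test_missing_transporter_gets_ortholog_suggestion(self):
        a = make_toy_bundle("A")
        b = make_toy_bundle("B")
        b.transport_reactions = {}
        b.genes["bx"] = Gene(id="bx")
        orthologs = OrthologTable([(("A", "zt1"), ("B", "bx"))])
        inv = transporter_comparison([a, b], "arg", orthologs)
        assert [(s.gene, s.source_gene) for s in inv["B"].suggestions] == [
            ("bx", "zt1")
        ]


class TestDbStats:
    def test_empty_bundle_all_zero(self):
        row = db_stats(OrganismBundle(org_id="e"))
        assert (
            row.n_genes == row.n_pathways == row.n_transport_reactions
            == row.n_go_annotations == row.n_genes_exp == 0
        )

    def test_counts_on_toy_bundle(self):
        row = db_stats(make_toy_bundle())
        assert row.n_genes == 5
        assert row.n_pathways == 2
        assert row.n_transport_reactions == 1
        assert row.n_go_annotations == 2
        assert row.n_genes_with_molecular_function == 2
        assert row.n_pathways_exp == 1  # only ARG-PWY has curator evidence
        # g1: experimental enzyme evidence and an IDA annotation
        assert row.n_genes_exp == 1

    def test_experimental_counts_bounded_by_totals(self):
        from funcdash.fixtures import WorldParams, make_world

        world = make_world(WorldParams(seed=5))
        for b in world.bundles:
            row = db_stats(b)
            assert row.n_genes_exp <= row.n_genes
            assert row.n_pathways_exp <= row.n_pathways
            assert row.n_transport_exp <= row.n_transport_reactions


class TestSearch:
    @pytest.fixture
    def dashboard(self, dags):
        a = make_toy_bundle("orgA")
        b = make_toy_bundle("orgB")
        del b.pathways_present["ARG-PWY"]
        return build_dashboard([a, b], TestBuildDashboard.tree(), dags)

    def test_compound_found_with_cells_highlighted(self, dashboard):
        hits = search(dashboard, "arg")
        assert [h.panel_id for h in hits] == ["aa-syn"]
        assert hits[0].matched_cells == (("arg", "orgA"),)

    def test_absent_id_returns_empty_list(self, dashboard):
        assert search(dashboard, "zzz-nothing") == []

    def test_pathway_id_matches_via_provenance(self, dashboard):
        hits = search(dashboard, "TRE-PWY")
        assert {h.panel_id for h in hits} == {"sugar-syn"}

    def test_gene_in_two_subsystems_returns_both_panels(self, dags):
        # one gene annotated into two GO subsystems
        from funcdash.core_model import GOAnnotation
        from funcdash.subsystems import PanelNode, SubsystemSpec

        a = make_toy_bundle("orgA")
        b = make_toy_bundle("orgB")
        for org in (a, b):
            org.go_annotations = [
                GOAnnotation(gene_id="p1", term_id="GO:C"),
                GOAnnotation(gene_id="p1", term_id="GO:E"),
            ]
        tree = [
            PanelNode(
                id="panel",
                label="P",
                level="top",
                children=[
                    PanelNode(
                        id=f"sub-{t}",
                        label=f"Sub {t}",
                        spec=SubsystemSpec(
                            id=f"sub-{t}", label=t, kind="go", term_ids=(t,)
                        ),
                    )
                    for t in ("GO:C", "GO:E")
                ],
            )
        ]
        dash = build_dashboard([a, b], tree, dags)
        hits = search(dash, "p1")
        assert {h.panel_id for h in hits} == {"sub-GO:C", "sub-GO:E"}

    def test_name_matching_and_substring_flag(self, dashboard):
        # whole-word name match on the compound label
        assert search(dashboard, "trehalose")
        assert not search(dashboard, "trehal")
        assert search(dashboard, "trehal", substring=True)
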