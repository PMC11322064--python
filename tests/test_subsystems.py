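"""Tally engine: pathway/transport/GO subsystems, scoring, dashboard assembly."""

from __future__ import annotations

import random

import pytest

from funcdash.core_model import (
    GOAnnotation,
    Gene,
    OrganismBundle,
    Pathway,
    Reaction,
    TransportReaction,
)
from funcdash.subsystems import (
    CompoundCell,
    ConfigurationError,
    PanelNode,
    SubsystemSpec,
    build_dashboard,
    compound_cell_score,
    default_panel_tree,
    go_direct_counts,
    go_subsystem_genes,
    pathway_presence_matrix,
    pathway_score,
    pathway_subsystem_compounds,
    transport_subsystem,
)
from tests.conftest import make_toy_bundle

AA_SPEC = SubsystemSpec(
    id="aa-syn",
    label="Amino Acid Syn",
    kind="pathway",
    pathway_class="AA-Biosynthesis",
    metabolite_class="AminoAcids",
    direction="outputs",
)


class TestPathwayScore:
    def test_noncomputational_evidence_scores_one(self):
        reactions = {
            f"r{i}": Reaction(id=f"r{i}", enzyme_gene_ids=("g",) if i == 0 else ())
            for i in range(5)
        }
        pwy = Pathway(
            id="p",
            reaction_ids=tuple(reactions),
            evidence=frozenset({"non-computational"}),
            base_score=0.2,
        )
        assert pathway_score(pwy, reactions) == 1.0

    def test_no_enzymes_no_base_score_is_zero(self):
        reactions = {f"r{i}": Reaction(id=f"r{i}") for i in range(4)}
        pwy = Pathway(id="p", reaction_ids=tuple(reactions))
        assert pathway_score(pwy, reactions) == 0.0

    def test_max_of_base_and_coverage(self):
        reactions = {
            f"r{i}": Reaction(id=f"r{i}", enzyme_gene_ids=("g",) if i < 3 else ())
            for i in range(4)
        }
        pwy = Pathway(id="p", reaction_ids=tuple(reactions), base_score=0.5)
        assert pathway_score(pwy, reactions) == pytest.approx(0.75)

    def test_base_score_wins_when_coverage_low(self):
        reactions = {f"r{i}": Reaction(id=f"r{i}") for i in range(4)}
        pwy = Pathway(id="p", reaction_ids=tuple(reactions), base_score=0.6)
        assert pathway_score(pwy, reactions) == pytest.approx(0.6)

    def test_zero_reactions_is_error(self):
        with pytest.raises(ValueError, match="zero reactions"):
            pathway_score(Pathway(id="p"), {})

    @pytest.mark.parametrize("seed", range(3))
    def test_random_fixtures_match_hand_formula(self, seed):
        rng = random.Random(seed)
        for _ in range(200):
            n = rng.randint(1, 8)
            covered = rng.randint(0, n)
            reactions = {
                f"r{i}": Reaction(
                    id=f"r{i}", enzyme_gene_ids=("g",) if i < covered else ()
                )
                for i in range(n)
            }
            noncomp = rng.random() < 0.3
            base = round(rng.random(), 3) if rng.random() < 0.5 else None
            pwy = Pathway(
                id="p",
                reaction_ids=tuple(reactions),
                evidence=frozenset(
                    {"non-computational"} if noncomp else {"computational"}
                ),
                base_score=base,
            )
            expected = 1.0 if noncomp else max(base or 0.0, covered / n)
            got = pathway_score(pwy, reactions)
            assert got == pytest.approx(expected)
            assert 0.0 <= got <= 1.0

    def test_removing_enzymes_never_raises_score(self):
        rng = random.Random(11)
        for _ in range(50):
            n = rng.randint(1, 6)
            covered = rng.randint(1, n)
            mk = lambda c: {
                f"r{i}": Reaction(
                    id=f"r{i}", enzyme_gene_ids=("g",) if i < c else ()
                )
                for i in range(n)
            }
            pwy = Pathway(
                id="p",
                reaction_ids=tuple(f"r{i}" for i in range(n)),
                base_score=round(rng.random(), 2),
            )
            assert pathway_score(pwy, mk(covered - 1)) <= pathway_score(
                pwy, mk(covered)
            )


class TestPathwaySubsystem:
    def test_designated_product_tallied(self, dags, toy_bundle):
        cells = pathway_subsystem_compounds(toy_bundle, AA_SPEC, dags)
        assert set(cells) == {"arg"}
        assert cells["arg"].pathways == ("ARG-PWY",)
        assert cells["arg"].score == 1.0  # curator evidence

    def test_empty_bundle_empty_tally(self, dags):
        empty = OrganismBundle(org_id="empty")
        assert pathway_subsystem_compounds(empty, AA_SPEC, dags) == {}

    def test_compound_outside_metabolite_class_excluded(self, dags, toy_bundle):
        # TRE-PWY produces tre (a sugar): excluded from the amino-acid subsystem
        cells = pathway_subsystem_compounds(toy_bundle, AA_SPEC, dags)
        assert "tre" not in cells

    def test_two_pathways_one_compound_both_in_provenance(self, dags):
        b = make_toy_bundle()
        b.reactions["r5"] = Reaction(
            id="r5", reactant_ids=("x",), product_ids=("arg",)
        )
        b.pathways_present["ARG-PWY2"] = Pathway(
            id="ARG-PWY2",
            class_ids=("AA-Biosynthesis",),
            reaction_ids=("r5",),
            primary_reactants=("x",),
            primary_products=("arg",),
        )
        cells = pathway_subsystem_compounds(b, AA_SPEC, dags)
        assert cells["arg"].pathways == ("ARG-PWY", "ARG-PWY2")

    def test_unknown_class_is_configuration_error(self, dags, toy_bundle):
        bad = SubsystemSpec(
            id="x",
            label="x",
            kind="pathway",
            pathway_class="No-Such-Class",
            metabolite_class="AminoAcids",
            direction="outputs",
        )
        with pytest.raises(ConfigurationError):
            pathway_subsystem_compounds(toy_bundle, bad, dags)

    def test_adding_pathway_never_shrinks_tally(self, dags):
        b = make_toy_bundle()
        before = set(pathway_subsystem_compounds(b, AA_SPEC, dags))
        b.reactions["r6"] = Reaction(
            id="r6", reactant_ids=("y",), product_ids=("trp",)
        )
        b.pathways_present["TRP-PWY"] = Pathway(
            id="TRP-PWY",
            class_ids=("AA-Biosynthesis",),
            reaction_ids=("r6",),
            primary_reactants=("y",),
            primary_products=("trp",),
        )
        after = set(pathway_subsystem_compounds(b, AA_SPEC, dags))
        assert before <= after


def test_compound_cell_score_is_max_over_pathways():
    cell = CompoundCell(score=0.0, pathways=("p1", "p2", "p3"))
    scores = {"p1": 0.4, "p2": 1.0, "p3": 0.1}
    assert compound_cell_score(cell, scores) == 1.0
    rng = random.Random(3)
    for _ in range(20):
        vals = {f"p{i}": rng.random() for i in range(5)}
        cell = CompoundCell(score=0.0, pathways=tuple(vals))
        assert compound_cell_score(cell, vals) == pytest.approx(max(vals.values()))


class TestTransportSubsystem:
    @staticmethod
    def spec(cls):
        return SubsystemSpec(
            id=f"tr-{cls}", label=cls, kind="transport", compound_class=cls
        )

    def test_substrate_in_class_listed_with_transporters(self, dags, toy_bundle):
        cells = transport_subsystem(toy_bundle, self.spec("AminoAcids"), dags)
        assert set(cells) == {"arg"}
        assert cells["arg"].transporters == (("zt1",),)

    def test_substrate_outside_configured_classes_goes_to_other(self, dags):
        b = make_toy_bundle()
        b.genes["u1"] = Gene(id="u1")
        b.transport_reactions["T2"] = TransportReaction(
            id="T2", primary_substrate="unknown_ion", transporter_gene_ids=("u1",)
        )
        other = SubsystemSpec(
            id="other", label="Other", kind="transport", compound_class="OTHER"
        )
        cells = transport_subsystem(
            b, other, dags, configured_classes=["AminoAcids", "Sugars"]
        )
        assert set(cells) == {"unknown_ion"}
        in_class = transport_subsystem(b, self.spec("AminoAcids"), dags)
        assert "unknown_ion" not in in_class

    def test_transporter_count_is_number_of_reactions(self, dags):
        b = make_toy_bundle()
        for i in (2, 3):
            b.genes[f"zt{i}"] = Gene(id=f"zt{i}")
            b.transport_reactions[f"T{i}"] = TransportReaction(
                id=f"T{i}", primary_substrate="arg", transporter_gene_ids=(f"zt{i}",)
            )
        cells = transport_subsystem(b, self.spec("AminoAcids"), dags)
        assert cells["arg"].count == 3

    def test_multi_class_compound_appears_under_each_class(self, dags):
        b = make_toy_bundle()
        b.genes["d1"] = Gene(id="d1")
        b.transport_reactions["TD"] = TransportReaction(
            id="TD", primary_substrate="dual", transporter_gene_ids=("d1",)
        )
        for cls in ("AminoAcids", "Sugars"):
            assert "dual" in transport_subsystem(b, self.spec(cls), dags)
        other = SubsystemSpec(
            id="other", label="Other", kind="transport", compound_class="OTHER"
        )
        assert "dual" not in transport_subsystem(
            b, other, dags, configured_classes=["AminoAcids", "Sugars"]
        )


class TestGOSubsystem:
    @staticmethod
    def spec(terms, exceptions=()):
        return SubsystemSpec(
            id="go-s",
            label="s",
            kind="go",
            term_ids=tuple(terms),
            exception_term_ids=tuple(exceptions),
        )

    def test_child_term_annotation_included(self, go_dag, toy_bundle):
        # g1 annotated to GO:D, a descendant of designated GO:A
        col = go_subsystem_genes(toy_bundle, self.spec(["GO:A"]), go_dag)
        assert "g1" in col.genes

    def test_exception_closure_excluded(self, go_dag):
        b = make_toy_bundle()
        col = go_subsystem_genes(b, self.spec(["GO:A"], ["GO:B"]), go_dag)
        # p1 -> GO:B and g1 -> GO:D are both inside the GO:B exception closure
        assert col.genes == frozenset()

    def test_excluded_gene_reappears_via_other_included_term(self, go_dag):
        b = make_toy_bundle()
        b.go_annotations.append(GOAnnotation(gene_id="p1", term_id="GO:C"))
        col = go_subsystem_genes(b, self.spec(["GO:A"], ["GO:B"]), go_dag)
        assert col.genes == {"p1"}

    def test_not_qualified_annotations_never_count(self, go_dag):
        b = make_toy_bundle()
        b.go_annotations = [
            GOAnnotation(gene_id="p1", term_id="GO:B", qualifier="NOT")
        ]
        col = go_subsystem_genes(b, self.spec(["GO:A"]), go_dag)
        assert col.genes == frozenset()

    def test_gene_with_two_terms_counted_once_in_set_twice_in_rows(self, go_dag):
        b = make_toy_bundle()
        b.go_annotations = [
            GOAnnotation(gene_id="p1", term_id="GO:B"),
            GOAnnotation(gene_id="p1", term_id="GO:C"),
        ]
        col = go_subsystem_genes(b, self.spec(["GO:A"]), go_dag)
        assert col.genes == {"p1"}
        assert col.direct == {"GO:B": frozenset({"p1"}), "GO:C": frozenset({"p1"})}

    def test_direct_counts_exclude_descendant_annotations(self, go_dag):
        b = make_toy_bundle()
        b.go_annotations = [
            GOAnnotation(gene_id="p1", term_id="GO:B"),
            GOAnnotation(gene_id="g1", term_id="GO:D"),
        ]
        direct = go_direct_counts(b, self.spec(["GO:A"]), go_dag)
        # g1 is annotated only to the child GO:D: it must not inflate GO:B
        assert direct["GO:B"] == frozenset({"p1"})
        assert direct["GO:D"] == frozenset({"g1"})

    def test_direct_sets_subset_of_gene_set(self, go_dag):
        b = make_toy_bundle()
        col = go_subsystem_genes(b, self.spec(["GO:0"]), go_dag)
        for genes in col.direct.values():
            assert genes <= col.genes

    def test_unknown_term_is_configuration_error(self, go_dag, toy_bundle):
        with pytest.raises(ConfigurationError):
            go_subsystem_genes(toy_bundle, self.spec(["GO:NOPE"]), go_dag)


class TestPresenceMatrix:
    def test_variant_satisfies_class_via_closure(self, dags):
        b = make_toy_bundle()
        b.reactions["rt"] = Reaction(id="rt", reactant_ids=("a",), product_ids=("b",))
        b.pathways_present["TCA-V1"] = Pathway(
            id="TCA-V1",
            class_ids=("TCA-Variant",),
            reaction_ids=("rt",),
            primary_reactants=(),
            primary_products=(),
        )
        m = pathway_presence_matrix([b], ["TCA"], dags)
        assert bool(m.loc["orgA", "TCA"])

    def test_no_pathways_all_false(self, dags):
        empty = OrganismBundle(org_id="e")
        m = pathway_presence_matrix([empty], ["TCA"], dags)
        assert not m.to_numpy().any()

    def test_direct_pathway_id_category(self, dags, toy_bundle):
        m = pathway_presence_matrix([toy_bundle], ["ARG-PWY"], dags)
        assert bool(m.loc["orgA", "ARG-PWY"])

    def test_unresolvable_category_is_error(self, dags, toy_bundle):
        with pytest.raises(ConfigurationError, match="Nonexistent"):
            pathway_presence_matrix([toy_bundle], ["Nonexistent"], dags)


class TestBuildDashboard:
    @staticmethod
    def tree():
        return [
            PanelNode(
                id="bio",
                label="Biosynthesis",
                level="top",
                children=[
                    PanelNode(id="aa-syn", label="AA Syn", spec=AA_SPEC),
                    PanelNode(
                        id="sugar-syn",
                        label="Sugar Syn",
                        spec=SubsystemSpec(
                            id="sugar-syn",
                            label="Sugar Syn",
                            kind="pathway",
                            pathway_class="Sugar-Biosynthesis",
                            metabolite_class="Sugars",
                            direction="outputs",
                        ),
                    ),
                ],
            ),
            PanelNode(
                id="go-panel",
                label="Processes",
                level="top",
                children=[
                    PanelNode(
                        id="proc-a",
                        label="Process A",
                        spec=SubsystemSpec(
                            id="proc-a", label="Process A", kind="go",
                            term_ids=("GO:A",),
                        ),
                    )
                ],
            ),
        ]

    def test_base_counts_and_union_at_parent(self, dags):
        a = make_toy_bundle("orgA")
        b = make_toy_bundle("orgB")
        del b.pathways_present["TRE-PWY"]
        dash = build_dashboard([a, b], self.tree(), dags)
        bio = dash.panels[0]
        assert bio.counts == {"orgA": 2, "orgB": 1}  # union of {arg} and {tre}
        assert bio.item_sets["orgA"] == {"arg", "tre"}

    def test_parent_union_not_sum_when_children_overlap(self, dags):
        # same compound tallied by two sibling subsystems counts once upward
        a = make_toy_bundle("orgA")
        tree = self.tree()
        dup = PanelNode(
            id="aa-syn-2",
            label="AA Syn again",
            spec=SubsystemSpec(
                id="aa-syn-2", label="x", kind="pathway",
                pathway_class="AA-Biosynthesis", metabolite_class="AminoAcids",
                direction="outputs",
            ),
        )
        tree[0].children.append(dup)
        dash = build_dashboard([a], tree, dags)
        assert dash.panels[0].counts["orgA"] == 2  # arg once, tre once

    def test_empty_subsystem_omitted_nonempty_kept(self, dags):
        a = make_toy_bundle("orgA")
        a.go_annotations = []
        b = make_toy_bundle("orgB")
        b.go_annotations = []
        dash = build_dashboard([a, b], self.tree(), dags)
        states = {n.id: n.omitted for n in dash.iter_base()}
        assert states["proc-a"] is True
        assert states["aa-syn"] is False
        assert dash.panels[1].omitted  # whole GO panel empty -> omitted

    def test_single_organism_with_data_keeps_plot_others_zero(self, dags):
        a = make_toy_bundle("orgA")
        b = make_toy_bundle("orgB")
        b.go_annotations = []
        dash = build_dashboard([a, b], self.tree(), dags)
        node = dash.find("proc-a")
        assert not node.omitted
        assert node.counts == {"orgA": 2, "orgB": 0}

    def test_duplicate_org_ids_rejected(self, dags):
        a = make_toy_bundle("orgA")
        with pytest.raises(ValueError, match="unique"):
            build_dashboard([a, make_toy_bundle("orgA")], self.tree(), dags)

    def test_empty_tree_rejected(self, dags, toy_bundle):
        with pytest.raises(ConfigurationError):
            build_dashboard([toy_bundle], [], dags)

    def test_grid_rows_sorted_by_prevalence_then_name(self, dags):
        a = make_toy_bundle("orgA")
        b = make_toy_bundle("orgB")
        del b.pathways_present["ARG-PWY"]  # arg in 1 org, tre in 2
        tree = self.tree()
        dash = build_dashboard([a, b], tree, dags)
        rows_aa = dash.find("aa-syn").tally.grid.rows
        assert rows_aa == ["arg"]
        # two items, same prevalence -> alphabetical
        dash1 = build_dashboard([a], tree, dags)
        assert dash1.panels[0].children[0].tally.grid.rows == ["arg"]


def test_default_panel_tree_loads_and_has_standard_panels():
    tree = default_panel_tree()
    ids = [p.id for p in tree]
    assert "biosynthesis" in ids and "transport" in ids and "virulence" in ids
    base = [b for p in tree for b in p.iter_base()]
    kinds = {b.spec.kind for b in base}
    assert kinds == {"pathway", "transport", "go", "pathway-presence-matrix"}
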