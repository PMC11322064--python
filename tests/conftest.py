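"""Shared fixtures: tiny hand-built ontologies and bundles.

All fixture data is generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import logging

import pytest

from funcdash.core_model import (
    GOAnnotation,
    Gene,
    OntologyDAG,
    OrganismBundle,
    Pathway,
    Reaction,
    TransportReaction,
)

logging.getLogger("funcdash").setLevel(logging.ERROR)


@pytest.fixture
def compound_dag() -> OntologyDAG:
    """Compounds: root -> {AminoAcids -> {arg, trp}, Sugars -> {tre, glc}};
    'dual' sits under both classes."""
    return OntologyDAG(
        {
            "Compounds": [],
            "AminoAcids": ["Compounds"],
            "Sugars": ["Compounds"],
            "arg": ["AminoAcids"],
            "trp": ["AminoAcids"],
            "tre": ["Sugars"],
            "glc": ["Sugars"],
            "dual": ["AminoAcids", "Sugars"],
        },
        labels={"arg": "arginine", "tre": "trehalose", "glc": "glucose"},
        namespace="compound-class",
    )


@pytest.fixture
def pathway_dag() -> OntologyDAG:
    return OntologyDAG(
        {
            "Pathways": [],
            "Biosynthesis": ["Pathways"],
            "AA-Biosynthesis": ["Biosynthesis"],
            "Sugar-Biosynthesis": ["Biosynthesis"],
            "Degradation": ["Pathways"],
            "AA-Degradation": ["Degradation"],
            "TCA": ["Pathways"],
            "TCA-Variant": ["TCA"],
        },
        namespace="pathway-class",
    )


@pytest.fixture
def go_dag() -> OntologyDAG:
    """root -> A -> {B -> D, C}; E under root."""
    return OntologyDAG(
        {
            "GO:0": [],
            "GO:A": ["GO:0"],
            "GO:B": ["GO:A"],
            "GO:C": ["GO:A"],
            "GO:D": ["GO:B"],
            "GO:E": ["GO:0"],
        },
        labels={"GO:A": "process a", "GO:B": "process b"},
        namespace="go",
    )


@pytest.fixture
def dags(compound_dag, pathway_dag, go_dag):
    return {
        "compound-class": compound_dag,
        "pathway-class": pathway_dag,
        "go": go_dag,
    }


def make_toy_bundle(org_id: str = "orgA") -> OrganismBundle:
    """One organism with an arginine biosynthesis pathway (2 of 2 reactions
    enzyme-covered), a partial trehalose pathway, a Zn transporter and two
    GO annotations."""
    genes = {
        "g1": Gene(id="g1", name="argA", molecular_function_assigned=True),
        "g2": Gene(id="g2", name="argB", molecular_function_assigned=True),
        "g3": Gene(id="g3", name="treY"),
        "zt1": Gene(id="zt1", name="znuA"),
        "p1": Gene(id="p1", name="soj"),
    }
    reactions = {
        "r1": Reaction(
            id="r1",
            reactant_ids=("pre",),
            product_ids=("mid",),
            enzyme_gene_ids=("g1",),
            enzyme_evidence={"g1": "experimental"},
        ),
        "r2": Reaction(
            id="r2",
            reactant_ids=("mid",),
            product_ids=("arg",),
            enzyme_gene_ids=("g2",),
            enzyme_evidence={"g2": "computational"},
        ),
        "r3": Reaction(
            id="r3",
            reactant_ids=("glc",),
            product_ids=("tre",),
            enzyme_gene_ids=("g3",),
            enzyme_evidence={"g3": "computational"},
        ),
        "r4": Reaction(id="r4", reactant_ids=("tre",), product_ids=("out",)),
    }
    pathways = {
        "ARG-PWY": Pathway(
            id="ARG-PWY",
            name="arginine biosynthesis",
            class_ids=("AA-Biosynthesis",),
            reaction_ids=("r1", "r2"),
            primary_reactants=("pre",),
            primary_products=("arg",),
            evidence=frozenset({"computational", "non-computational"}),
        ),
        "TRE-PWY": Pathway(
            id="TRE-PWY",
            name="trehalose biosynthesis",
            class_ids=("Sugar-Biosynthesis",),
            reaction_ids=("r3", "r4"),
            primary_products=("tre",),
            primary_reactants=("glc",),
            evidence=frozenset({"computational"}),
            base_score=0.4,
        ),
    }
    transport = {
        "T1": TransportReaction(
            id="T1", primary_substrate="arg", transporter_gene_ids=("zt1",)
        ),
    }
    annotations = [
        GOAnnotation(gene_id="p1", term_id="GO:B", evidence_code="IEA"),
        GOAnnotation(gene_id="g1", term_id="GO:D", evidence_code="IDA"),
    ]
    return OrganismBundle(
        org_id=org_id,
        display_name=f"Toy organism {org_id}",
        genes=genes,
        reactions=reactions,
        pathways_present=pathways,
        transport_reactions=transport,
        go_annotations=annotations,
        metadata={"version": "1.0", "curation_tier": "curated"},
    )


@pytest.fixture
def toy_bundle() -> OrganismBundle:
    return make_toy_bundle()
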