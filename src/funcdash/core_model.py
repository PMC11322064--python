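"""Ontology and organism-bundle data model.

The central objects are :class:`OntologyDAG` -- a rooted, acyclic is-a
hierarchy used for pathway classes, compound classes and GO terms -- and
:class:`OrganismBundle`, one organism's functional annotation: genes,
reactions with enzyme assignments, pathways with presence evidence and
optional predictor scores, transport reactions with primary substrates,
and GO annotations.

Closure queries (``descendant_closure``, ``is_member``) and primary
reactant/product resolution (``primary_sides``) live here; everything
downstream (subsystem tallies, overlays, comparison tables) is built on
these primitives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: GO evidence codes treated as computational when deciding whether an
#: annotation counts as "non-computational" evidence.  Overridable per call.
COMPUTATIONAL_EVIDENCE_CODES = frozenset({"IEA", "ISS", "ISA", "ISM", "ISO"})

#: GO evidence codes treated as experimental for database statistics.
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "HTP", "HDA", "HMP", "HGI", "HEP"}
)


class OntologyError(ValueError):
    """Raised for structural problems in an ontology (cycles, bad refs)."""


class UnknownTermError(KeyError):
    """Raised when a term id is not present in an ontology."""

    def __init__(self, term: str, namespace: str):
        super().__init__(term)
        self.term = term
        self.namespace = namespace

    def __str__(self) -> str:  # noqa: D105
        return f"unknown term {self.term!r} in {self.namespace} ontology"


class OntologyDAG:
    """A rooted directed acyclic is-a hierarchy.

    Edges are stored child -> parent (OBO ``is_a`` convention); closures are
    computed in the parent -> descendants direction.  Compounds are modeled
    as leaves of the compound-class DAG.

    Parameters
    ----------
    parents
        Mapping of term id to its parent term ids.  Roots map to an empty
        collection.  Every referenced parent must itself be a key.
    labels
        Optional display names per term.
    namespace
        One of ``"pathway-class"``, ``"compound-class"``, ``"go"``.
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[str]],
        labels: Mapping[str, str] | None = None,
        namespace: str = "go",
    ):
        self.namespace = namespace
        self.parents: dict[str, frozenset[str]] = {
            t: frozenset(ps) for t, ps in parents.items()
        }
        self.labels: dict[str, str] = dict(labels or {})
        # parent -> child edges, so nx.descendants walks downward
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise OntologyError(
                        f"{namespace}: term {child!r} names parent {p!r} "
                        "absent from the ontology"
                    )
                g.add_edge(p, child)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(
                f"{namespace}: is-a hierarchy contains a cycle: "
                + " -> ".join(str(u) for u, _ in cycle)
            )
        self._graph = g

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    def label(self, term: str) -> str:
        return self.labels.get(term, term)

    def children(self, term: str) -> frozenset[str]:
        if term not in self.parents:
            raise UnknownTermError(term, self.namespace)
        return frozenset(self._graph.successors(term))

    def roots(self) -> frozenset[str]:
        return frozenset(t for t, ps in self.parents.items() if not ps)

    def descendant_closure(self, term: str) -> frozenset[str]:
        """Return ``term`` plus all of its descendants (child-closure)."""
        if term not in self.parents:
            raise UnknownTermError(term, self.namespace)
        return frozenset(nx.descendants(self._graph, term)) | {term}

    def is_member(self, compound: str, cls: str) -> bool:
        """True iff ``compound`` lies in the descendant closure of ``cls``.

        Compounds unknown to the ontology are members of no class; a
        warning is logged once per lookup so miscounts are not silent.
        """
        if cls not in self.parents:
            raise UnknownTermError(cls, self.namespace)
        if compound not in self.parents:
            logger.warning(
                "%s: compound %r not in ontology; treated as member of no class",
                self.namespace,
                compound,
            )
            return False
        return compound in self.descendant_closure(cls)


def descendant_closure(dag: OntologyDAG, term: str) -> frozenset[str]:
    """Module-level alias for :meth:`OntologyDAG.descendant_closure`."""
    return dag.descendant_closure(term)


def is_member(dag: OntologyDAG, compound: str, cls: str) -> bool:
    """Module-level alias for :meth:`OntologyDAG.is_member`."""
    return dag.is_member(compound, cls)


# ---------------------------------------------------------------------------
# Bundle record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gene:
    id: str
    name: str = ""
    product_type: str = "protein"
    molecular_function_assigned: bool = False


@dataclass(frozen=True)
class Reaction:
    """A reaction with the enzymes assigned to it in one organism.

    ``enzyme_evidence`` maps gene id -> ``"experimental"`` or
    ``"computational"``; genes without an entry default to computational.
    """

    id: str
    reactant_ids: tuple[str, ...] = ()
    product_ids: tuple[str, ...] = ()
    enzyme_gene_ids: tuple[str, ...] = ()
    enzyme_evidence: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Pathway:
    """A pathway instance marked present in an organism.

    ``evidence`` holds the kinds of supporting evidence records:
    ``"computational"`` and/or ``"non-computational"``.  ``base_score`` is
    the 0-1 confidence assigned by the upstream pathway predictor, if any.
    """

    id: str
    name: str = ""
    class_ids: tuple[str, ...] = ()
    reaction_ids: tuple[str, ...] = ()
    primary_reactants: tuple[str, ...] | None = None
    primary_products: tuple[str, ...] | None = None
    evidence: frozenset[str] = frozenset({"computational"})
    base_score: float | None = None
    key_reactions: tuple[str, ...] = ()
    unique_reactions: tuple[str, ...] = ()

    def __post_init__(self):
        if self.base_score is not None and not 0.0 <= self.base_score <= 1.0:
            raise ValueError(
                f"pathway {self.id}: base_score {self.base_score} outside [0, 1]"
            )
        extra = (set(self.key_reactions) | set(self.unique_reactions)) - set(
            self.reaction_ids
        )
        if extra:
            raise ValueError(
                f"pathway {self.id}: key/unique reactions {sorted(extra)} "
                "not among the pathway's reactions"
            )

    @property
    def has_noncomputational_evidence(self) -> bool:
        return "non-computational" in self.evidence


@dataclass(frozen=True)
class TransportReaction:
    """A transport reaction; the transporter may be a multi-gene complex."""

    id: str
    primary_substrate: str
    transporter_gene_ids: tuple[str, ...]
    evidence: str = "computational"

    def __post_init__(self):
        if not self.primary_substrate:
            raise ValueError(f"transport reaction {self.id}: no primary substrate")
        if not self.transporter_gene_ids:
            raise ValueError(f"transport reaction {self.id}: no transporter genes")


@dataclass(frozen=True)
class GOAnnotation:
    gene_id: str
    term_id: str
    qualifier: str = "plain"  # "plain" or "NOT"
    evidence_code: str = "IEA"

    @property
    def is_not(self) -> bool:
        return self.qualifier == "NOT"


@dataclass
class OrganismBundle:
    """One organism's annotation: the unit of comparison.

    Mirrors the content of an organism-specific pathway/genome database:
    genes, reactions with enzyme links, pathways asserted present, transport
    reactions, and GO annotations, plus provenance metadata (database
    version and curation tier).
    """

    org_id: str
    display_name: str = ""
    color: str | None = None
    genes: dict[str, Gene] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    pathways_present: dict[str, Pathway] = field(default_factory=dict)
    transport_reactions: dict[str, TransportReaction] = field(default_factory=dict)
    go_annotations: list[GOAnnotation] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.display_name:
            self.display_name = self.org_id

    def positive_go_annotations(self) -> list[GOAnnotation]:
        """GO annotations excluding NOT-qualified records."""
        return [a for a in self.go_annotations if not a.is_not]


# ---------------------------------------------------------------------------
# Primary reactant/product resolution
# ---------------------------------------------------------------------------


def primary_sides(
    pathway: Pathway,
    reactions: Mapping[str, Reaction],
    currency_metabolites: Iterable[str] = (),
) -> tuple[frozenset[str], frozenset[str]]:
    """Resolve a pathway's primary reactants and products.

    Curator designations, when present, are returned verbatim.  Otherwise
    both sides are inferred from the pathway's reaction list by the
    net-terminal rule: a primary reactant is consumed by some reaction and
    produced by none; a primary product is produced by some reaction and
    consumed by none.  Compounds listed in ``currency_metabolites`` are
    ignored by the inference.

    Returns ``(reactants, products)`` as frozen sets of compound ids.
    """
    if pathway.primary_reactants is not None and pathway.primary_products is not None:
        return frozenset(pathway.primary_reactants), frozenset(pathway.primary_products)
    if not pathway.reaction_ids:
        raise ValueError(
            f"pathway {pathway.id}: no reactions and no designated primary sides"
        )
    currency = frozenset(currency_metabolites)
    consumed: set[str] = set()
    produced: set[str] = set()
    for rid in pathway.reaction_ids:
        rxn = reactions.get(rid)
        if rxn is None:
            raise KeyError(f"pathway {pathway.id}: unknown reaction {rid!r}")
        consumed.update(set(rxn.reactant_ids) - currency)
        produced.update(set(rxn.product_ids) - currency)
    reactants = frozenset(
        pathway.primary_reactants
        if pathway.primary_reactants is not None
        else consumed - produced
    )
    products = frozenset(
        pathway.primary_products
        if pathway.primary_products is not None
        else produced - consumed
    )
    return reactants, products


# ---------------------------------------------------------------------------
# Bundle validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" or "warning"
    locus: str  # JSON-pointer-like path into the bundle
    message: str

    def __str__(self) -> str:  # noqa: D105
        return f"[{self.severity}] {self.locus}: {self.message}"


def validate_bundle(
    bundle: OrganismBundle,
    dags: Mapping[str, OntologyDAG] | None = None,
) -> list[ValidationIssue]:
    """Check all cross-references and invariants of a bundle.

    ``dags`` may supply ontologies keyed ``"go"``, ``"compound-class"`` and
    ``"pathway-class"``; references into an absent ontology are not checked.
    Returns a list of issues -- empty iff the bundle is well-formed.
    """
    dags = dags or {}
    issues: list[ValidationIssue] = []

    def err(locus: str, message: str):
        issues.append(ValidationIssue("error", locus, message))

    def warn(locus: str, message: str):
        issues.append(ValidationIssue("warning", locus, message))

    go = dags.get("go")
    pwy_classes = dags.get("pathway-class")

    for pid, pwy in bundle.pathways_present.items():
        locus = f"/pathways_present/{pid}"
        for rid in pwy.reaction_ids:
            if rid not in bundle.reactions:
                err(locus, f"pathway {pid} references missing reaction {rid!r}")
        if pwy.base_score is not None and not 0.0 <= pwy.base_score <= 1.0:
            err(locus, f"base_score {pwy.base_score} outside [0, 1]")
        if pwy_classes is not None:
            for cid in pwy.class_ids:
                if cid not in pwy_classes:
                    err(locus, f"unknown pathway class {cid!r}")

    for rid, rxn in bundle.reactions.items():
        locus = f"/reactions/{rid}"
        for g in rxn.enzyme_gene_ids:
            if g not in bundle.genes:
                err(locus, f"reaction {rid} names unknown enzyme gene {g!r}")

    for tid, trxn in bundle.transport_reactions.items():
        locus = f"/transport_reactions/{tid}"
        if not trxn.transporter_gene_ids:
            err(locus, "transport reaction has no transporter genes")
        for g in trxn.transporter_gene_ids:
            if g not in bundle.genes:
                err(locus, f"transport reaction names unknown gene {g!r}")

    for i, ann in enumerate(bundle.go_annotations):
        locus = f"/go_annotations/{i}"
        if ann.gene_id not in bundle.genes:
            warn(locus, f"annotation for unknown gene {ann.gene_id!r}")
        if go is not None and ann.term_id not in go:
            err(locus, f"annotation to unknown GO term {ann.term_id!r}")

    return issues
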