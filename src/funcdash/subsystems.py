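"""Subsystem definitions and the tally engine.

A *subsystem* is the base unit of the dashboard.  Three kinds exist:

* **pathway** -- the combination of a pathway class *P*, a metabolite class
  *M* and a direction *D* (inputs for degradation families, outputs for
  biosynthesis families).  Its tally for an organism is the set of primary
  compounds, on side *D*, of pathways present in the organism that
  instantiate a class in the closure of *P*, filtered to members of *M*.
* **transport** -- a compound class *C*; its tally is the set of primary
  substrates of the organism's transport reactions that fall in *C*, with
  transporter inventories per compound.  The reserved class ``OTHER``
  collects substrates belonging to none of the configured classes.
* **go** -- one or more GO terms with an optional exception list; its tally
  is the set of genes annotated (non-NOT) to any designated term or its
  descendants, minus the closure of the exception terms.

Subsystems are arranged in a panel tree (top panels -> optional
intermediate panels -> base panels); :func:`build_dashboard` decorates the
tree with per-organism tallies, aggregating upward by set union and
omitting nodes that are empty in every organism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from funcdash.core_model import (
    OntologyDAG,
    OrganismBundle,
    Pathway,
    Reaction,
    UnknownTermError,
    primary_sides,
)

OTHER_CLASS = "OTHER"


class ConfigurationError(ValueError):
    """Raised when a subsystem or panel configuration is invalid."""


# ---------------------------------------------------------------------------
# Specs and panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubsystemSpec:
    """Definition of a base subsystem (see module docstring)."""

    id: str
    label: str
    kind: str  # "pathway" | "transport" | "go" | "pathway-presence-matrix"
    # pathway kind
    pathway_class: str | None = None
    metabolite_class: str | None = None
    direction: str | None = None  # "inputs" | "outputs"
    # transport kind
    compound_class: str | None = None  # may be OTHER_CLASS
    # go kind
    term_ids: tuple[str, ...] = ()
    exception_term_ids: tuple[str, ...] = ()
    # pathway-presence-matrix kind
    categories: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind == "pathway":
            if not (self.pathway_class and self.metabolite_class and self.direction):
                raise ConfigurationError(
                    f"subsystem {self.id}: pathway kind needs pathway_class, "
                    "metabolite_class and direction"
                )
            if self.direction not in ("inputs", "outputs"):
                raise ConfigurationError(
                    f"subsystem {self.id}: direction must be 'inputs' or 'outputs'"
                )
        elif self.kind == "transport":
            if not self.compound_class:
                raise ConfigurationError(
                    f"subsystem {self.id}: transport kind needs compound_class"
                )
        elif self.kind == "go":
            if not self.term_ids:
                raise ConfigurationError(
                    f"subsystem {self.id}: go kind needs at least one term id"
                )
        elif self.kind == "pathway-presence-matrix":
            if not self.categories:
                raise ConfigurationError(
                    f"subsystem {self.id}: presence-matrix kind needs categories"
                )
        else:
            raise ConfigurationError(f"subsystem {self.id}: unknown kind {self.kind!r}")


@dataclass
class PanelNode:
    """A node in the panel hierarchy.

    Base nodes wrap exactly one :class:`SubsystemSpec` via ``spec``;
    top and intermediate nodes carry children instead.
    """

    id: str
    label: str
    children: list["PanelNode"] = field(default_factory=list)
    spec: SubsystemSpec | None = None
    level: str = ""  # "top" | "intermediate" | "base"; derived if empty

    def __post_init__(self):
        if self.spec is not None and self.children:
            raise ConfigurationError(
                f"panel {self.id}: base nodes wrap one subsystem, no children"
            )
        if not self.level:
            self.level = "base" if self.spec is not None else "intermediate"

    def iter_base(self) -> Iterable["PanelNode"]:
        if self.spec is not None:
            yield self
        for child in self.children:
            yield from child.iter_base()


# ---------------------------------------------------------------------------
# Tally cells and grids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundCell:
    """One (compound, organism) cell of a pathway or transport grid."""

    score: float
    pathways: tuple[str, ...] = ()
    transporters: tuple[tuple[str, ...], ...] = ()

    @property
    def count(self) -> int:
        return len(self.transporters) if self.transporters else len(self.pathways)

    @property
    def provenance(self) -> tuple[str, ...]:
        if self.transporters:
            return tuple("+".join(t) for t in self.transporters)
        return self.pathways


@dataclass(frozen=True)
class GOCell:
    """One (GO term, organism) cell: the directly annotated genes."""

    genes: tuple[str, ...]

    @property
    def score(self) -> float:
        return 1.0

    @property
    def count(self) -> int:
        return len(self.genes)

    @property
    def provenance(self) -> tuple[str, ...]:
        return self.genes


@dataclass
class GOTallyColumn:
    """One organism's GO-subsystem tally."""

    genes: frozenset[str]
    direct: dict[str, frozenset[str]]  # used term -> directly annotated genes


@dataclass
class ComparisonGrid:
    """Rows (compounds or GO terms) x columns (organisms) of cells."""

    kind: str
    organisms: list[str]
    rows: list[str]
    row_labels: dict[str, str]
    cells: dict[tuple[str, str], CompoundCell | GOCell]  # (row, org) -> cell

    def cell(self, row: str, org: str):
        return self.cells.get((row, org))

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame (rows x organisms); 0 where absent."""
        data = {
            org: [
                (c.count if (c := self.cells.get((r, org))) is not None else 0)
                for r in self.rows
            ]
            for org in self.organisms
        }
        return pd.DataFrame(data, index=self.rows)


def _sorted_rows(per_org_items: Mapping[str, Iterable[str]]) -> list[str]:
    """Grid row order: descending #organisms possessing, then alphabetical."""
    counts: dict[str, int] = {}
    for items in per_org_items.values():
        for item in items:
            counts[item] = counts.get(item, 0) + 1
    return sorted(counts, key=lambda item: (-counts[item], item))


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def pathway_score(pathway: Pathway, reactions: Mapping[str, Reaction]) -> float:
    """Confidence score in [0, 1] for a pathway's presence.

    A pathway carrying non-computational evidence (i.e. its presence was
    verified by a curator) scores exactly 1.0 regardless of enzyme
    coverage.  Otherwise the score is the maximum of the predictor-assigned
    base score and the fraction of the pathway's reactions that have at
    least one enzyme identified.
    """
    if pathway.has_noncomputational_evidence:
        return 1.0
    n = len(pathway.reaction_ids)
    if n == 0:
        raise ValueError(f"pathway {pathway.id}: score undefined with zero reactions")
    covered = sum(
        1
        for rid in pathway.reaction_ids
        if (rxn := reactions.get(rid)) is not None and rxn.enzyme_gene_ids
    )
    return max(pathway.base_score or 0.0, covered / n)


def compound_cell_score(cell: CompoundCell, scores: Mapping[str, float]) -> float:
    """Max pathway score over a cell's supporting pathways.

    ``scores`` maps pathway id -> pathway_score for the same organism.
    Drives box opacity in rendered grids.
    """
    if not cell.pathways:
        return cell.score
    return max(scores[p] for p in cell.pathways)


# ---------------------------------------------------------------------------
# Per-subsystem tallies
# ---------------------------------------------------------------------------


def pathway_subsystem_compounds(
    bundle: OrganismBundle,
    spec: SubsystemSpec,
    dags: Mapping[str, OntologyDAG],
    currency_metabolites: Iterable[str] = (),
) -> dict[str, CompoundCell]:
    """Tally the compounds of a pathway-based subsystem for one organism.

    For every pathway present in the bundle that instantiates a class in
    the closure of the subsystem's pathway class, take its primary
    reactants (direction ``inputs``) or products (``outputs``) and keep the
    members of the subsystem's metabolite class.  Each compound's cell
    records every supporting pathway and the max pathway score.
    """
    if spec.kind != "pathway":
        raise ConfigurationError(f"subsystem {spec.id} is not pathway-based")
    pwy_dag = dags["pathway-class"]
    cpd_dag = dags["compound-class"]
    try:
        p_closure = pwy_dag.descendant_closure(spec.pathway_class)
    except UnknownTermError as exc:
        raise ConfigurationError(str(exc)) from exc
    if spec.metabolite_class not in cpd_dag:
        raise ConfigurationError(
            f"subsystem {spec.id}: unknown metabolite class {spec.metabolite_class!r}"
        )
    m_closure = cpd_dag.descendant_closure(spec.metabolite_class)

    support: dict[str, list[str]] = {}
    best: dict[str, float] = {}
    for pwy in bundle.pathways_present.values():
        if p_closure.isdisjoint(pwy.class_ids):
            continue
        reactants, products = primary_sides(
            pwy, bundle.reactions, currency_metabolites
        )
        side = reactants if spec.direction == "inputs" else products
        score = None
        for c in side:
            if c not in cpd_dag:
                # unknown to the compound ontology: member of no class
                cpd_dag.is_member(c, spec.metabolite_class)  # logs the warning
                continue
            if c not in m_closure:
                continue
            if score is None:
                score = pathway_score(pwy, bundle.reactions)
            support.setdefault(c, []).append(pwy.id)
            best[c] = max(best.get(c, 0.0), score)
    return {
        c: CompoundCell(score=best[c], pathways=tuple(sorted(pwys)))
        for c, pwys in support.items()
    }


def transport_subsystem(
    bundle: OrganismBundle,
    spec: SubsystemSpec,
    dags: Mapping[str, OntologyDAG],
    configured_classes: Iterable[str] = (),
) -> dict[str, CompoundCell]:
    """Tally transported compounds of a transport subsystem for one organism.

    A compound is tallied when it is the primary substrate of a transport
    reaction and a member of the subsystem's compound class; its cell lists
    every transporter (each a gene-id tuple, possibly a complex).  For the
    reserved ``OTHER`` subsystem, pass the full set of configured transport
    classes: substrates belonging to none of them are tallied there.
    """
    if spec.kind != "transport":
        raise ConfigurationError(f"subsystem {spec.id} is not transport-based")
    cpd_dag = dags["compound-class"]
    is_other = spec.compound_class == OTHER_CLASS
    if not is_other and spec.compound_class not in cpd_dag:
        raise ConfigurationError(
            f"subsystem {spec.id}: unknown compound class {spec.compound_class!r}"
        )

    def belongs(cpd: str) -> bool:
        if cpd not in cpd_dag:
            # unknown substrates belong to no configured class, only OTHER
            return is_other
        if is_other:
            return not any(
                cls in cpd_dag and cpd_dag.is_member(cpd, cls)
                for cls in configured_classes
            )
        return cpd_dag.is_member(cpd, spec.compound_class)

    carriers: dict[str, list[tuple[str, ...]]] = {}
    for trxn in sorted(bundle.transport_reactions.values(), key=lambda t: t.id):
        cpd = trxn.primary_substrate
        if belongs(cpd):
            carriers.setdefault(cpd, []).append(tuple(trxn.transporter_gene_ids))
    return {
        c: CompoundCell(score=1.0, transporters=tuple(ts))
        for c, ts in carriers.items()
    }


def go_included_terms(spec: SubsystemSpec, go_dag: OntologyDAG) -> frozenset[str]:
    """Included-term set: union of designated closures minus exception closures."""
    included: set[str] = set()
    for t in spec.term_ids:
        try:
            included |= go_dag.descendant_closure(t)
        except UnknownTermError as exc:
            raise ConfigurationError(str(exc)) from exc
    for e in spec.exception_term_ids:
        try:
            included -= go_dag.descendant_closure(e)
        except UnknownTermError as exc:
            raise ConfigurationError(str(exc)) from exc
    return frozenset(included)


def go_subsystem_genes(
    bundle: OrganismBundle,
    spec: SubsystemSpec,
    go_dag: OntologyDAG,
) -> GOTallyColumn:
    """Tally the genes of a GO-based subsystem for one organism.

    The gene set contains every gene with at least one non-NOT annotation
    to an included term (designated terms and their descendants, minus the
    exception closure).  Direct counts are kept per used term: a gene
    annotated to two included terms appears once in the subsystem gene set
    but once per term in the direct counts.
    """
    if spec.kind != "go":
        raise ConfigurationError(f"subsystem {spec.id} is not GO-based")
    included = go_included_terms(spec, go_dag)
    genes: set[str] = set()
    direct: dict[str, set[str]] = {}
    for ann in bundle.positive_go_annotations():
        if ann.term_id in included:
            genes.add(ann.gene_id)
            direct.setdefault(ann.term_id, set()).add(ann.gene_id)
    return GOTallyColumn(
        genes=frozenset(genes),
        direct={t: frozenset(gs) for t, gs in direct.items()},
    )


def go_direct_counts(
    bundle: OrganismBundle,
    spec: SubsystemSpec,
    go_dag: OntologyDAG,
) -> dict[str, frozenset[str]]:
    """Direct-annotation gene sets per used term for one organism.

    A gene counts toward a term only if annotated to that term itself --
    genes annotated only to descendants are excluded (they count toward the
    descendant's own row).
    """
    return go_subsystem_genes(bundle, spec, go_dag).direct


def pathway_presence_matrix(
    bundles: Sequence[OrganismBundle],
    categories: Sequence[str],
    dags: Mapping[str, OntologyDAG],
) -> pd.DataFrame:
    """Boolean organisms x categories matrix of pathway presence.

    Each category is a pathway-class id (any present pathway instantiating
    a class in its closure counts, so e.g. every variant of a cycle
    satisfies the cycle's class) or a concrete pathway id.
    """
    pwy_dag = dags["pathway-class"]
    known_pathways = {
        pid for b in bundles for pid in b.pathways_present
    }
    closures: dict[str, frozenset[str] | None] = {}
    for cat in categories:
        if cat in pwy_dag:
            closures[cat] = pwy_dag.descendant_closure(cat)
        elif cat in known_pathways:
            closures[cat] = None  # direct pathway id
        else:
            raise ConfigurationError(
                f"presence-matrix category {cat!r} is neither a pathway class "
                "nor a pathway present in any bundle"
            )
    rows = {}
    for b in bundles:
        row = {}
        for cat in categories:
            closure = closures[cat]
            if closure is None:
                row[cat] = cat in b.pathways_present
            else:
                row[cat] = any(
                    not closure.isdisjoint(p.class_ids)
                    for p in b.pathways_present.values()
                )
        rows[b.org_id] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(categories))


# ---------------------------------------------------------------------------
# Dashboard assembly
# ---------------------------------------------------------------------------


@dataclass
class SubsystemTally:
    """Per-organism tallies for one base subsystem, plus its grid."""

    spec: SubsystemSpec
    item_sets: dict[str, frozenset[str]]  # org -> compound/gene ids
    counts: dict[str, int]
    grid: ComparisonGrid
    go_columns: dict[str, GOTallyColumn] | None = None
    presence: pd.DataFrame | None = None


@dataclass
class DecoratedNode:
    """A panel-tree node decorated with per-organism tallies."""

    id: str
    label: str
    level: str
    children: list["DecoratedNode"]
    tally: SubsystemTally | None
    item_sets: dict[str, frozenset[str]]
    counts: dict[str, int]
    omitted: bool

    def iter_base(self) -> Iterable["DecoratedNode"]:
        if self.tally is not None:
            yield self
        for child in self.children:
            yield from child.iter_base()


@dataclass
class Dashboard:
    """The fully decorated comparison: the engine's end product."""

    organisms: list[str]  # org ids, display order
    display_names: dict[str, str]
    panels: list[DecoratedNode]
    bundles: dict[str, OrganismBundle]
    dags: Mapping[str, OntologyDAG]

    def iter_base(self) -> Iterable[DecoratedNode]:
        for panel in self.panels:
            yield from panel.iter_base()

    def find(self, node_id: str) -> DecoratedNode | None:
        def walk(node: DecoratedNode):
            if node.id == node_id:
                return node
            for child in node.children:
                if (found := walk(child)) is not None:
                    return found
            return None

        for panel in self.panels:
            if (found := walk(panel)) is not None:
                return found
        return None


def _transport_classes(tree: Sequence[PanelNode]) -> list[str]:
    classes = []
    for panel in tree:
        for base in panel.iter_base():
            s = base.spec
            if s.kind == "transport" and s.compound_class != OTHER_CLASS:
                classes.append(s.compound_class)
    return classes


def _tally_base(
    spec: SubsystemSpec,
    bundles: Sequence[OrganismBundle],
    dags: Mapping[str, OntologyDAG],
    transport_classes: Sequence[str],
    currency_metabolites: Iterable[str],
) -> SubsystemTally:
    orgs = [b.org_id for b in bundles]
    if spec.kind in ("pathway", "transport"):
        per_org: dict[str, dict[str, CompoundCell]] = {}
        for b in bundles:
            if spec.kind == "pathway":
                per_org[b.org_id] = pathway_subsystem_compounds(
                    b, spec, dags, currency_metabolites
                )
            else:
                per_org[b.org_id] = transport_subsystem(
                    b, spec, dags, transport_classes
                )
        rows = _sorted_rows({o: cells.keys() for o, cells in per_org.items()})
        cpd_dag = dags["compound-class"]
        grid = ComparisonGrid(
            kind=spec.kind,
            organisms=orgs,
            rows=rows,
            row_labels={r: cpd_dag.label(r) if r in cpd_dag else r for r in rows},
            cells={
                (r, o): per_org[o][r]
                for o in orgs
                for r in rows
                if r in per_org[o]
            },
        )
        item_sets = {o: frozenset(per_org[o]) for o in orgs}
        counts = {o: len(item_sets[o]) for o in orgs}
        return SubsystemTally(spec, item_sets, counts, grid)

    if spec.kind == "go":
        go_dag = dags["go"]
        columns = {b.org_id: go_subsystem_genes(b, spec, go_dag) for b in bundles}
        per_org_terms = {o: col.direct.keys() for o, col in columns.items()}
        rows = _sorted_rows(per_org_terms)
        grid = ComparisonGrid(
            kind="go",
            organisms=orgs,
            rows=rows,
            row_labels={r: go_dag.label(r) for r in rows},
            cells={
                (r, o): GOCell(genes=tuple(sorted(columns[o].direct[r])))
                for o in orgs
                for r in rows
                if r in columns[o].direct
            },
        )
        item_sets = {o: columns[o].genes for o in orgs}
        counts = {o: len(item_sets[o]) for o in orgs}
        return SubsystemTally(spec, item_sets, counts, grid, go_columns=columns)

    if spec.kind == "pathway-presence-matrix":
        presence = pathway_presence_matrix(bundles, list(spec.categories), dags)
        rows = list(spec.categories)
        pwy_dag = dags["pathway-class"]
        grid = ComparisonGrid(
            kind="pathway-presence-matrix",
            organisms=orgs,
            rows=rows,
            row_labels={r: pwy_dag.label(r) if r in pwy_dag else r for r in rows},
            cells={
                (r, o): CompoundCell(score=1.0, pathways=(r,))
                for o in orgs
                for r in rows
                if bool(presence.loc[o, r])
            },
        )
        item_sets = {
            o: frozenset(r for r in rows if bool(presence.loc[o, r])) for o in orgs
        }
        counts = {o: len(item_sets[o]) for o in orgs}
        return SubsystemTally(spec, item_sets, counts, grid, presence=presence)

    raise ConfigurationError(f"subsystem {spec.id}: unknown kind {spec.kind!r}")


def build_dashboard(
    bundles: Sequence[OrganismBundle],
    panel_tree: Sequence[PanelNode],
    dags: Mapping[str, OntologyDAG],
    currency_metabolites: Iterable[str] = (),
) -> Dashboard:
    """Tally every subsystem for every organism and decorate the panel tree.

    Parent nodes aggregate by set *union* of their children's item sets, so
    a compound produced by pathways in two sibling subsystems is counted
    once at the parent.  A node is omitted iff every organism's tally under
    it is empty.  One bundle is allowed (single-organism dashboard mode);
    comparison overlays require at least two.
    """
    if not panel_tree:
        raise ConfigurationError("empty panel tree")
    if not bundles:
        raise ValueError("at least one organism bundle is required")
    org_ids = [b.org_id for b in bundles]
    if len(set(org_ids)) != len(org_ids):
        raise ValueError("organism ids must be unique within a comparison set")

    transport_classes = _transport_classes(panel_tree)
    orgs = list(org_ids)

    def decorate(node: PanelNode, level: str) -> DecoratedNode:
        if node.spec is not None:
            tally = _tally_base(
                node.spec, bundles, dags, transport_classes, currency_metabolites
            )
            omitted = all(not s for s in tally.item_sets.values())
            return DecoratedNode(
                id=node.id,
                label=node.label,
                level="base",
                children=[],
                tally=tally,
                item_sets=tally.item_sets,
                counts=tally.counts,
                omitted=omitted,
            )
        children = [decorate(c, "intermediate") for c in node.children]
        item_sets = {
            o: frozenset().union(*(c.item_sets.get(o, frozenset()) for c in children))
            if children
            else frozenset()
            for o in orgs
        }
        counts = {o: len(item_sets[o]) for o in orgs}
        omitted = all(c.omitted for c in children) if children else True
        return DecoratedNode(
            id=node.id,
            label=node.label,
            level=level,
            children=children,
            tally=None,
            item_sets=item_sets,
            counts=counts,
            omitted=omitted,
        )

    panels = [decorate(p, "top") for p in panel_tree]
    return Dashboard(
        organisms=orgs,
        display_names={b.org_id: b.display_name for b in bundles},
        panels=panels,
        bundles={b.org_id: b for b in bundles},
        dags=dags,
    )


# ---------------------------------------------------------------------------
# Panel configuration (versioned JSON)
# ---------------------------------------------------------------------------

CONFIG_VERSION = 1


def _spec_from_dict(d: Mapping) -> SubsystemSpec:
    kind = d.get("kind")
    common = {"id": d["id"], "label": d.get("label", d["id"]), "kind": kind}
    if kind == "pathway":
        return SubsystemSpec(
            **common,
            pathway_class=d["pathway_class"],
            metabolite_class=d["metabolite_class"],
            direction=d["direction"],
        )
    if kind == "transport":
        return SubsystemSpec(**common, compound_class=d["compound_class"])
    if kind == "go":
        return SubsystemSpec(
            **common,
            term_ids=tuple(d["term_ids"]),
            exception_term_ids=tuple(d.get("exception_term_ids", ())),
        )
    if kind == "pathway-presence-matrix":
        return SubsystemSpec(**common, categories=tuple(d["categories"]))
    raise ConfigurationError(f"subsystem {d.get('id')!r}: unknown kind {kind!r}")


def _node_from_dict(d: Mapping, level: str) -> PanelNode:
    if "subsystem" in d:
        sub = dict(d["subsystem"])
        sub.setdefault("id", d["id"])
        sub.setdefault("label", d.get("label", d["id"]))
        return PanelNode(
            id=d["id"], label=d.get("label", d["id"]), spec=_spec_from_dict(sub)
        )
    children = [_node_from_dict(c, "intermediate") for c in d.get("children", [])]
    return PanelNode(
        id=d["id"], label=d.get("label", d["id"]), children=children, level=level
    )


def panel_tree_from_config(config: Mapping) -> list[PanelNode]:
    """Build a panel tree from a parsed configuration mapping."""
    version = config.get("config_version")
    if version != CONFIG_VERSION:
        raise ConfigurationError(
            f"unsupported panel config_version {version!r} (expected {CONFIG_VERSION})"
        )
    return [_node_from_dict(p, "top") for p in config["panels"]]


def load_panel_config(path) -> list[PanelNode]:
    """Load a panel tree from a versioned JSON configuration file."""
    with open(path, encoding="utf-8") as fh:
        return panel_tree_from_config(json.load(fh))


def _spec_to_dict(spec: SubsystemSpec) -> dict:
    d: dict = {"kind": spec.kind}
    if spec.kind == "pathway":
        d.update(
            pathway_class=spec.pathway_class,
            metabolite_class=spec.metabolite_class,
            direction=spec.direction,
        )
    elif spec.kind == "transport":
        d["compound_class"] = spec.compound_class
    elif spec.kind == "go":
        d["term_ids"] = list(spec.term_ids)
        if spec.exception_term_ids:
            d["exception_term_ids"] = list(spec.exception_term_ids)
    elif spec.kind == "pathway-presence-matrix":
        d["categories"] = list(spec.categories)
    return d


def _node_to_dict(node: PanelNode) -> dict:
    d: dict = {"id": node.id, "label": node.label}
    if node.spec is not None:
        d["subsystem"] = _spec_to_dict(node.spec)
    else:
        d["children"] = [_node_to_dict(c) for c in node.children]
    return d


def panel_config_from_tree(tree: Sequence[PanelNode]) -> dict:
    """Serialize a panel tree back to the versioned JSON configuration form."""
    return {
        "config_version": CONFIG_VERSION,
        "panels": [_node_to_dict(p) for p in tree],
    }


def save_panel_config(tree: Sequence[PanelNode], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(panel_config_from_tree(tree), fh, indent=1, sort_keys=True)
        fh.write("\n")


def default_panel_tree() -> list[PanelNode]:
    """The shipped default panel configuration.

    Mirrors the standard dashboard layout (Biosynthesis, Degradation/
    Utilization/Assimilation, Energy Metabolism, Transport, Central Dogma,
    Response to Stimulus, Cellular Processes, Virulence-Related, Cell
    Exterior).  The GO term lists cover the documented examples only; the
    file is user-editable (see docs/panel_config.md).
    """
    ref = resources.files("funcdash").joinpath("data/default_panels.json")
    return panel_tree_from_config(json.loads(ref.read_text(encoding="utf-8")))
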