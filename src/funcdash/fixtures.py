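"""Deterministic synthetic-world generator.

Builds ontologies, organism bundles, similarity-hit tables and a matching
panel tree with controlled overlap structure, so every engine operation is
testable without external downloads.  Alongside the data, the generator
records an *expected-answer ledger* -- ground-truth tallies, cell scores,
overlay counts, pathway scores and ortholog pairs -- computed
constructively by bookkeeping during generation, never by running the
tally engine.  The ledger therefore serves as an independent oracle for
end-to-end tests.

The synthetic world emulates the shape of real per-organism annotation
databases (compound classes with member compounds, pathway classes with
biosynthesis/degradation pathways of varying enzyme coverage and evidence,
transporter inventories, a small GO-like DAG with per-gene annotations)
but makes no attempt to mimic real pathway content or real GO ids.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from funcdash.comparison import HitRecord
from funcdash.core_model import (
    GOAnnotation,
    Gene,
    OntologyDAG,
    OrganismBundle,
    Pathway,
    Reaction,
    TransportReaction,
)
from funcdash.subsystems import (
    OTHER_CLASS,
    PanelNode,
    SubsystemSpec,
)


@dataclass(frozen=True)
class OverlapDesign:
    """Forced overlap structure for one subsystem.

    ``common`` compounds go to every organism, ``unique[i]`` compounds to
    organism *i* alone, and ``shared`` compounds to a random strict subset
    of size >= 2.  Requires ``common + sum(unique) + shared`` to fit within
    the class's compound count.
    """

    common: int
    unique: tuple[int, ...]
    shared: int = 0


@dataclass(frozen=True)
class WorldParams:
    """Knobs of the synthetic world; defaults give a small mixed world."""

    seed: int = 0
    n_organisms: int = 4
    n_compound_classes: int = 3
    compounds_per_class: int = 8
    n_pathways: int = 30
    reactions_per_pathway: tuple[int, int] = (2, 5)
    pathway_presence_prob: float = 0.5
    enzyme_coverage: tuple[float, float] = (0.3, 1.0)
    noncomputational_evidence_prob: float = 0.15
    base_score_prob: float = 0.5
    second_pathway_prob: float = 0.2
    transported_per_class: int = 3
    orphan_substrates: int = 2
    n_energy_categories: int = 3
    energy_presence_prob: float = 0.5
    go_depth: int = 3
    go_terms: int = 24
    n_go_subsystems: int = 3
    genes_per_org: int = 30
    annotations_per_gene: float = 1.5
    not_annotation_prob: float = 0.05
    ortholog_fraction: float = 0.3
    #: overlap designs keyed by (kind, class index) with kind "bio" or "deg"
    overlap_design: Mapping[tuple[str, int], OverlapDesign] | None = None
    #: organism indices left without any GO annotation
    go_less_org_indices: tuple[int, ...] = ()
    #: (org index, n genes, subsystem label): a GO gene block present in one
    #: organism only (e.g. a sporulation-like block)
    single_org_go_block: tuple[int, int, str] | None = None
    #: org index given an exclusive energy category (photosynthesis-like)
    single_org_energy_category: int | None = None

    def __post_init__(self):
        for p in (
            self.pathway_presence_prob,
            self.noncomputational_evidence_prob,
            self.base_score_prob,
            self.second_pathway_prob,
            self.energy_presence_prob,
            self.not_annotation_prob,
            self.ortholog_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if min(
            self.n_organisms,
            self.n_compound_classes,
            self.compounds_per_class,
            self.go_terms,
            self.genes_per_org,
        ) <= 0:
            raise ValueError("counts must be positive")


@dataclass
class World:
    """A generated world plus its ground-truth ledger."""

    params: WorldParams
    dags: dict[str, OntologyDAG]
    bundles: list[OrganismBundle]
    hits: list[HitRecord]
    panel_tree: list[PanelNode]
    ledger: dict


def _closure(children: Mapping[str, set[str]], term: str) -> set[str]:
    """Brute-force DFS closure over an explicit child map (oracle-grade)."""
    seen = {term}
    stack = [term]
    while stack:
        for child in children.get(stack.pop(), ()):
            if child not in seen:
                seen.add(child)
                stack.append(child)
    return seen


def _overlay_counts(item_sets: Mapping[str, set[str]]) -> dict:
    """Common/shared/unique by direct membership counting (bookkeeping)."""
    orgs = list(item_sets)
    members: dict[str, int] = {}
    for o in orgs:
        for item in item_sets[o]:
            members[item] = members.get(item, 0) + 1
    n = len(orgs)
    common = sum(1 for c in members.values() if c == n)
    unique = {}
    shared = {}
    total = {}
    for o in orgs:
        total[o] = len(item_sets[o])
        unique[o] = sum(1 for i in item_sets[o] if members[i] == 1)
        shared[o] = total[o] - common - unique[o]
    return {"common": common, "total": total, "shared": shared, "unique": unique}


def make_world(params: WorldParams | None = None) -> World:
    """Generate a synthetic world; same seed, same world, byte for byte."""
    p = params or WorldParams()
    rng = random.Random(p.seed)
    orgs = [f"org{chr(ord('A') + i)}" for i in range(p.n_organisms)]

    # ------------------------------------------------------------------ DAGs
    cpd_parents: dict[str, set[str]] = {"Compounds": set()}
    cpd_labels: dict[str, str] = {"Compounds": "compounds"}
    compound_classes = [f"Class-{i}" for i in range(p.n_compound_classes)]
    compounds: dict[int, list[str]] = {}
    compound_memberships: dict[str, set[str]] = {}
    for i, cls in enumerate(compound_classes):
        cpd_parents[cls] = {"Compounds"}
        cpd_labels[cls] = f"class {i} compounds"
        compounds[i] = []
        for j in range(p.compounds_per_class):
            cid = f"C{i}_{j}"
            cpd_parents[cid] = {cls}
            cpd_labels[cid] = f"compound {i}.{j}"
            compounds[i].append(cid)
            compound_memberships[cid] = {cls}
    # every 5th compound also belongs to the next class (multi-class case)
    if p.n_compound_classes > 1:
        for i, cls in enumerate(compound_classes):
            nxt = compound_classes[(i + 1) % p.n_compound_classes]
            for cid in compounds[i][::5]:
                cpd_parents[cid].add(nxt)
                compound_memberships[cid].add(nxt)

    pwy_parents: dict[str, set[str]] = {
        "Pathways": set(),
        "Biosynthesis": {"Pathways"},
        "Degradation": {"Pathways"},
        "Energy": {"Pathways"},
    }
    pwy_labels = {
        "Pathways": "pathways",
        "Biosynthesis": "biosynthesis",
        "Degradation": "degradation",
        "Energy": "energy metabolism",
    }
    for i in range(p.n_compound_classes):
        pwy_parents[f"Bio-Class-{i}"] = {"Biosynthesis"}
        pwy_labels[f"Bio-Class-{i}"] = f"class {i} biosynthesis"
        pwy_parents[f"Deg-Class-{i}"] = {"Degradation"}
        pwy_labels[f"Deg-Class-{i}"] = f"class {i} degradation"
    energy_categories = [f"Energy-Cat-{k}" for k in range(p.n_energy_categories)]
    if p.single_org_energy_category is not None:
        energy_categories.append("Photosynthesis-Cat")
    for cat in energy_categories:
        pwy_parents[cat] = {"Energy"}
        pwy_labels[cat] = cat.lower().replace("-", " ")
        pwy_parents[f"{cat}-Var"] = {cat}
        pwy_labels[f"{cat}-Var"] = f"variant of {cat.lower()}"

    # GO-like DAG: layered, occasionally diamond-shaped
    go_root = "GO:1000000"
    go_children: dict[str, set[str]] = {go_root: set()}
    go_parents: dict[str, set[str]] = {go_root: set()}
    go_labels = {go_root: "biological process"}
    levels: list[list[str]] = [[go_root]]
    term_no = 1
    while term_no < p.go_terms:
        depth = len(levels)
        if depth > p.go_depth:
            break
        width = min(p.go_terms - term_no, max(2, p.go_terms // p.go_depth))
        level = []
        for _ in range(width):
            t = f"GO:1{term_no:06d}"
            term_no += 1
            parent = rng.choice(levels[-1])
            go_parents[t] = {parent}
            go_children.setdefault(parent, set()).add(t)
            go_children.setdefault(t, set())
            if len(levels[-1]) > 1 and rng.random() < 0.15:
                extra = rng.choice(levels[-1])
                if extra != parent:
                    go_parents[t].add(extra)
                    go_children[extra].add(t)
            go_labels[t] = f"process {t[-4:]}"
            level.append(t)
        levels.append(level)

    dags = {
        "compound-class": OntologyDAG(
            cpd_parents, cpd_labels, namespace="compound-class"
        ),
        "pathway-class": OntologyDAG(
            pwy_parents, pwy_labels, namespace="pathway-class"
        ),
        "go": OntologyDAG(go_parents, go_labels, namespace="go"),
    }

    bundles = {
        org: OrganismBundle(
            org_id=org,
            display_name=f"Synthetic organism {org[-1]}",
            metadata={
                "version": f"1.{i}",
                "curation_tier": "curated" if i == 0 else "computational",
            },
        )
        for i, org in enumerate(orgs)
    }

    ledger: dict = {
        "subsystems": {},
        "cell_scores": {},
        "provenance": {},
        "transporter_counts": {},
        "go_direct": {},
        "overlay": {},
        "pathway_scores": {org: {} for org in orgs},
        "presence_matrix": {org: {} for org in orgs},
        "ortholog_pairs": [],
    }

    panel_bio = PanelNode(id="biosynthesis", label="Biosynthesis", level="top")
    panel_deg = PanelNode(id="degradation", label="Degradation", level="top")
    panel_transport = PanelNode(id="transport", label="Transport", level="top")
    panel_energy = PanelNode(id="energy", label="Energy", level="top")
    panel_go = PanelNode(id="processes", label="Cellular Processes", level="top")

    # ------------------------------------------------------- pathway worlds
    def org_subset_for(design_sizes: OverlapDesign | None, pool: list[str]):
        """Assign each compound in ``pool`` an organism subset."""
        assignment: dict[str, set[str]] = {}
        if design_sizes is None:
            for cid in pool:
                subset = {o for o in orgs if rng.random() < p.pathway_presence_prob}
                if subset:
                    assignment[cid] = subset
            return assignment
        d = design_sizes
        if len(d.unique) != len(orgs):
            raise ValueError("overlap design unique vector length != n_organisms")
        need = d.common + sum(d.unique) + d.shared
        if need > len(pool):
            raise ValueError(
                f"infeasible overlap design: needs {need} compounds, "
                f"class has {len(pool)}"
            )
        it = iter(pool)
        for _ in range(d.common):
            assignment[next(it)] = set(orgs)
        for oi, u in enumerate(d.unique):
            for _ in range(u):
                assignment[next(it)] = {orgs[oi]}
        for _ in range(d.shared):
            size = rng.randint(2, max(2, len(orgs) - 1))
            assignment[next(it)] = set(rng.sample(orgs, min(size, len(orgs) - 1)))
        return assignment

    pathway_budget = p.n_pathways
    rxn_counter = 0

    def build_pathway(
        pid: str,
        class_id: str,
        compound: str,
        direction: str,
        present_orgs: set[str],
        designate: bool,
    ):
        """Create one pathway definition and instantiate it per organism."""
        nonlocal rxn_counter
        n_rxn = rng.randint(*p.reactions_per_pathway)
        rids = []
        chain = [f"SRC_{pid}"] + [f"INT_{pid}_{k}" for k in range(n_rxn - 1)] + [
            compound
        ]
        if direction == "inputs":
            chain = [compound] + chain[1:-1] + [f"WASTE_{pid}"]
        rxn_defs = []
        for k in range(n_rxn):
            rid = f"RXN-{pid}-{k}"
            rids.append(rid)
            rxn_defs.append((rid, (chain[k],), (chain[k + 1],)))
            rxn_counter += 1
        primary_r = (chain[0],) if designate else None
        primary_p = (chain[-1],) if designate else None
        key = (rids[0],) if rng.random() < 0.3 else ()
        unique = (rids[-1],) if rng.random() < 0.3 else ()
        for org in orgs:
            if org not in present_orgs:
                continue
            b = bundles[org]
            lo, hi = p.enzyme_coverage
            coverage = rng.uniform(lo, hi)
            n_cov = round(coverage * n_rxn)
            covered = set(rng.sample(range(n_rxn), n_cov))
            for k, (rid, reac, prod) in enumerate(rxn_defs):
                enzymes: tuple[str, ...] = ()
                evidence = {}
                if k in covered:
                    g = f"g_{org}_{pid}_{k}"
                    b.genes[g] = Gene(
                        id=g, name=f"enzyme {pid}.{k}", molecular_function_assigned=True
                    )
                    enzymes = (g,)
                    evidence = {
                        g: "experimental" if rng.random() < 0.2 else "computational"
                    }
                b.reactions[rid] = Reaction(
                    id=rid,
                    reactant_ids=reac,
                    product_ids=prod,
                    enzyme_gene_ids=enzymes,
                    enzyme_evidence=evidence,
                )
            noncomp = rng.random() < p.noncomputational_evidence_prob
            base = (
                round(rng.uniform(0, 1), 2)
                if rng.random() < p.base_score_prob
                else None
            )
            b.pathways_present[pid] = Pathway(
                id=pid,
                name=f"pathway {pid}",
                class_ids=(class_id,),
                reaction_ids=tuple(rids),
                primary_reactants=primary_r,
                primary_products=primary_p,
                evidence=frozenset(
                    {"computational", "non-computational"}
                    if noncomp
                    else {"computational"}
                ),
                base_score=base,
                key_reactions=key,
                unique_reactions=unique,
            )
            score = 1.0 if noncomp else max(base or 0.0, n_cov / n_rxn)
            ledger["pathway_scores"][org][pid] = score

    designs = dict(p.overlap_design or {})
    for i in range(p.n_compound_classes):
        for kind, class_id, direction in (
            ("bio", f"Bio-Class-{i}", "outputs"),
            ("deg", f"Deg-Class-{i}", "inputs"),
        ):
            spec_id = f"{kind}-{i}"
            spec = SubsystemSpec(
                id=spec_id,
                label=f"{'Synthesis' if kind == 'bio' else 'Degradation'} class {i}",
                kind="pathway",
                pathway_class=class_id,
                metabolite_class=compound_classes[i],
                direction=direction,
            )
            parent = panel_bio if kind == "bio" else panel_deg
            parent.children.append(PanelNode(id=spec_id, label=spec.label, spec=spec))
            assignment = org_subset_for(designs.get((kind, i)), compounds[i])
            items: dict[str, set[str]] = {o: set() for o in orgs}
            scores: dict[str, dict[str, float]] = {o: {} for o in orgs}
            prov: dict[str, dict[str, list[str]]] = {o: {} for o in orgs}
            for cid in compounds[i]:
                if cid not in assignment or pathway_budget <= 0:
                    continue
                subset = assignment[cid]
                pids = [f"PWY-{spec_id}-{cid}"]
                presence = {pids[0]: set(subset)}
                if rng.random() < p.second_pathway_prob and pathway_budget > 1:
                    sub2 = {o for o in sorted(subset) if rng.random() < 0.5}
                    if sub2:
                        pid2 = f"PWY2-{spec_id}-{cid}"
                        pids.append(pid2)
                        presence[pid2] = sub2
                for pid in pids:
                    build_pathway(
                        pid,
                        class_id,
                        cid,
                        direction,
                        presence[pid],
                        designate=rng.random() < 0.5,
                    )
                    pathway_budget -= 1
                for org in sorted(subset):
                    supporting = sorted(
                        pid for pid in pids if org in presence[pid]
                    )
                    items[org].add(cid)
                    prov[org][cid] = supporting
                    scores[org][cid] = max(
                        ledger["pathway_scores"][org][pid] for pid in supporting
                    )
            ledger["subsystems"][spec_id] = {o: sorted(items[o]) for o in orgs}
            ledger["cell_scores"][spec_id] = scores
            ledger["provenance"][spec_id] = prov
            if len(orgs) >= 2:
                ledger["overlay"][spec_id] = _overlay_counts(items)

    # ------------------------------------------------------------ transport
    transport_items: dict[str, dict[str, set[str]]] = {}
    transport_counts: dict[str, dict[str, dict[str, int]]] = {}
    for i, cls in enumerate(compound_classes):
        spec_id = f"transport-{i}"
        spec = SubsystemSpec(
            id=spec_id,
            label=f"Transport class {i}",
            kind="transport",
            compound_class=cls,
        )
        panel_transport.children.append(
            PanelNode(id=spec_id, label=spec.label, spec=spec)
        )
        transport_items[spec_id] = {o: set() for o in orgs}
        transport_counts[spec_id] = {o: {} for o in orgs}
    other_id = "transport-other"
    panel_transport.children.append(
        PanelNode(
            id=other_id,
            label="Transport other",
            spec=SubsystemSpec(
                id=other_id,
                label="Transport other",
                kind="transport",
                compound_class=OTHER_CLASS,
            ),
        )
    )
    transport_items[other_id] = {o: set() for o in orgs}
    transport_counts[other_id] = {o: {} for o in orgs}

    t_counter = 0
    for org in orgs:
        b = bundles[org]
        substrates: list[str] = []
        for i in range(p.n_compound_classes):
            substrates += rng.sample(
                compounds[i], min(p.transported_per_class, len(compounds[i]))
            )
        for k in range(p.orphan_substrates):
            substrates.append(f"ORPHAN_{org}_{k}")
        for cpd in substrates:
            n_transporters = rng.randint(1, 3)
            for _ in range(n_transporters):
                tid = f"TR-{t_counter}"
                t_counter += 1
                n_genes = rng.randint(1, 2)
                gids = []
                for gi in range(n_genes):
                    g = f"t_{org}_{tid}_{gi}"
                    b.genes[g] = Gene(
                        id=g,
                        name=f"transporter {tid}.{gi}",
                        molecular_function_assigned=True,
                    )
                    gids.append(g)
                b.transport_reactions[tid] = TransportReaction(
                    id=tid,
                    primary_substrate=cpd,
                    transporter_gene_ids=tuple(gids),
                    evidence="experimental" if rng.random() < 0.1 else "computational",
                )
            classes = compound_memberships.get(cpd, set())
            spec_ids = (
                [f"transport-{compound_classes.index(c)}" for c in sorted(classes)]
                if classes
                else [other_id]
            )
            for sid in spec_ids:
                transport_items[sid][org].add(cpd)
                transport_counts[sid][org][cpd] = (
                    transport_counts[sid][org].get(cpd, 0) + n_transporters
                )
    for sid, items in transport_items.items():
        ledger["subsystems"][sid] = {o: sorted(items[o]) for o in orgs}
        ledger["transporter_counts"][sid] = transport_counts[sid]
        if len(orgs) >= 2:
            ledger["overlay"][sid] = _overlay_counts(items)

    # --------------------------------------------------------------- energy
    energy_spec = SubsystemSpec(
        id="energy-matrix",
        label="Energy pathway categories",
        kind="pathway-presence-matrix",
        categories=tuple(energy_categories),
    )
    panel_energy.children.append(
        PanelNode(id="energy-matrix", label=energy_spec.label, spec=energy_spec)
    )
    for cat in energy_categories:
        exclusive = (
            cat == "Photosynthesis-Cat" and p.single_org_energy_category is not None
        )
        for oi, org in enumerate(orgs):
            if exclusive:
                present = oi == p.single_org_energy_category
            else:
                present = rng.random() < p.energy_presence_prob
            ledger["presence_matrix"][org][cat] = present
            if not present:
                continue
            pid = f"PWY-{cat}-{org}"
            b = bundles[org]
            rids = []
            for k in range(2):
                rid = f"RXN-{pid}-{k}"
                rids.append(rid)
                g = f"g_{org}_{pid}_{k}"
                b.genes[g] = Gene(id=g, name=f"enzyme {pid}.{k}")
                b.reactions[rid] = Reaction(
                    id=rid,
                    reactant_ids=(f"E_{pid}_{k}",),
                    product_ids=(f"E_{pid}_{k + 1}",),
                    enzyme_gene_ids=(g,),
                    enzyme_evidence={g: "computational"},
                )
            b.pathways_present[pid] = Pathway(
                id=pid,
                name=f"energy pathway {pid}",
                class_ids=(f"{cat}-Var",),
                reaction_ids=tuple(rids),
                primary_reactants=(),
                primary_products=(),
            )
            ledger["pathway_scores"][org][pid] = 1.0  # full coverage, no evid. needed
    items = {
        o: {c for c, v in ledger["presence_matrix"][o].items() if v} for o in orgs
    }
    ledger["subsystems"]["energy-matrix"] = {o: sorted(items[o]) for o in orgs}

    # ------------------------------------------------------------------- GO
    all_terms = [t for lvl in levels for t in lvl]
    deep_terms = [t for lvl in levels[1:] for t in lvl]
    go_specs: list[SubsystemSpec] = []
    for s in range(p.n_go_subsystems):
        n_designated = rng.randint(1, 2)
        designated = tuple(rng.sample(levels[1], min(n_designated, len(levels[1]))))
        exceptions: tuple[str, ...] = ()
        if rng.random() < 0.5:
            candidates = sorted(
                set().union(*(_closure(go_children, t) for t in designated))
                - set(designated)
            )
            if candidates:
                exceptions = (rng.choice(candidates),)
        spec = SubsystemSpec(
            id=f"go-{s}",
            label=f"Process group {s}",
            kind="go",
            term_ids=designated,
            exception_term_ids=exceptions,
        )
        go_specs.append(spec)
        panel_go.children.append(PanelNode(id=spec.id, label=spec.label, spec=spec))

    included: dict[str, set[str]] = {}
    for spec in go_specs:
        inc = set()
        for t in spec.term_ids:
            inc |= _closure(go_children, t)
        for e in spec.exception_term_ids:
            inc -= _closure(go_children, e)
        included[spec.id] = inc

    go_gene_sets: dict[str, dict[str, set[str]]] = {
        spec.id: {o: set() for o in orgs} for spec in go_specs
    }
    go_direct: dict[str, dict[str, dict[str, set[str]]]] = {
        spec.id: {o: {} for o in orgs} for spec in go_specs
    }
    go_less = {orgs[i] for i in p.go_less_org_indices if i < len(orgs)}
    for org in orgs:
        if org in go_less:
            continue
        b = bundles[org]
        for gi in range(p.genes_per_org):
            g = f"p_{org}_{gi}"
            b.genes[g] = Gene(
                id=g,
                name=f"protein {gi}",
                molecular_function_assigned=rng.random() < 0.6,
            )
            n_ann = 1 + (1 if rng.random() < (p.annotations_per_gene - 1.0) else 0)
            for _ in range(n_ann):
                term = rng.choice(deep_terms)
                is_not = rng.random() < p.not_annotation_prob
                code = rng.choice(["IEA", "IEA", "ISS", "IDA", "IMP"])
                b.go_annotations.append(
                    GOAnnotation(
                        gene_id=g,
                        term_id=term,
                        qualifier="NOT" if is_not else "plain",
                        evidence_code=code,
                    )
                )
                if is_not:
                    continue
                for spec in go_specs:
                    if term in included[spec.id]:
                        go_gene_sets[spec.id][org].add(g)
                        go_direct[spec.id][org].setdefault(term, set()).add(g)

    if p.single_org_go_block is not None:
        oi, n_genes, label = p.single_org_go_block
        block_term = "GO:1999999"
        go_parents[block_term] = {go_root}
        go_children.setdefault(go_root, set()).add(block_term)
        go_labels[block_term] = label.lower()
        dags["go"] = OntologyDAG(go_parents, go_labels, namespace="go")
        spec = SubsystemSpec(
            id="go-block",
            label=label,
            kind="go",
            term_ids=(block_term,),
        )
        panel_go.children.append(PanelNode(id="go-block", label=label, spec=spec))
        go_specs.append(spec)
        go_gene_sets["go-block"] = {o: set() for o in orgs}
        go_direct["go-block"] = {o: {} for o in orgs}
        org = orgs[oi]
        b = bundles[org]
        for gi in range(n_genes):
            g = f"blk_{org}_{gi}"
            b.genes[g] = Gene(id=g, name=f"{label.lower()} protein {gi}")
            b.go_annotations.append(
                GOAnnotation(gene_id=g, term_id=block_term, evidence_code="IEA")
            )
            go_gene_sets["go-block"][org].add(g)
            go_direct["go-block"][org].setdefault(block_term, set()).add(g)

    for spec in go_specs:
        ledger["subsystems"][spec.id] = {
            o: sorted(go_gene_sets[spec.id][o]) for o in orgs
        }
        ledger["go_direct"][spec.id] = {
            o: {t: sorted(gs) for t, gs in sorted(go_direct[spec.id][o].items())}
            for o in orgs
        }

    # ----------------------------------------------------------------- hits
    hits: list[HitRecord] = []
    pair_ledger: list[list[list[str]]] = []
    for ai in range(len(orgs)):
        for bi in range(ai + 1, len(orgs)):
            a_org, b_org = orgs[ai], orgs[bi]
            a_genes = sorted(bundles[a_org].genes)
            b_genes = sorted(bundles[b_org].genes)
            n_pairs = int(p.ortholog_fraction * min(len(a_genes), len(b_genes)) / 2)
            a_pick = rng.sample(a_genes, min(n_pairs * 3, len(a_genes)))
            b_pick = rng.sample(b_genes, min(n_pairs * 3, len(b_genes)))
            k = 0
            for ga, gb in zip(a_pick, b_pick):
                if k < n_pairs:
                    # true reciprocal pair below threshold
                    e1 = 10 ** rng.uniform(-10, -4)
                    e2 = 10 ** rng.uniform(-10, -4)
                    hits.append(HitRecord(a_org, ga, b_org, gb, e1))
                    hits.append(HitRecord(b_org, gb, a_org, ga, e2))
                    pair_ledger.append(sorted([[a_org, ga], [b_org, gb]]))
                elif k < 2 * n_pairs:
                    # one-directional distractor
                    hits.append(
                        HitRecord(a_org, ga, b_org, gb, 10 ** rng.uniform(-8, -4))
                    )
                else:
                    # reciprocal but one side above threshold
                    hits.append(
                        HitRecord(a_org, ga, b_org, gb, 10 ** rng.uniform(-8, -4))
                    )
                    hits.append(
                        HitRecord(b_org, gb, a_org, ga, 10 ** rng.uniform(-2, 0))
                    )
                k += 1
    ledger["ortholog_pairs"] = sorted(pair_ledger)
    rng.shuffle(hits)

    panels = [panel_bio, panel_deg, panel_transport, panel_energy, panel_go]
    return World(
        params=p,
        dags=dags,
        bundles=[bundles[o] for o in orgs],
        hits=hits,
        panel_tree=panels,
        ledger=ledger,
    )


def make_demo_world() -> World:
    """A six-organism demo world echoing a full-range comparison.

    By construction: exactly one organism carries a sporulation-like GO
    gene block; one organism exclusively owns a photosynthesis-like energy
    pathway category; one organism is compound-class-0 poor (few class-0
    biosynthesis compounds); one organism carries no GO annotation at all;
    and the class-1 biosynthesis subsystem has five compounds common to
    all organisms plus at least one unique compound per organism.
    """
    n = 6
    design = {
        # class-0 biosynthesis: organism D (index 3) is poor in this class
        ("bio", 0): OverlapDesign(common=2, unique=(1, 1, 1, 0, 1, 1)),
        # class-1 biosynthesis: 5 common, 1 unique each (overlay showcase)
        ("bio", 1): OverlapDesign(common=5, unique=(1,) * n, shared=2),
    }
    params = WorldParams(
        seed=2024,
        n_organisms=n,
        n_compound_classes=4,
        compounds_per_class=14,
        n_pathways=90,
        pathway_presence_prob=0.5,
        overlap_design=design,
        go_less_org_indices=(2,),
        single_org_go_block=(1, 30, "Sporulation"),
        single_org_energy_category=5,
    )
    return make_world(params)


def write_world(world: World, out_dir) -> dict[str, Path]:
    """Write a world's inputs to disk in the formats the CLI consumes.

    Emits one bundle JSON per organism, the GO DAG as OBO, the class DAGs
    as JSON hierarchies, the hit table as tab-separated text, the panel
    configuration, and the ground-truth ledger as JSON.
    """
    import json

    from funcdash.io_formats import write_bundle, write_class_json, write_obo
    from funcdash.subsystems import save_panel_config

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for b in world.bundles:
        path = out / f"{b.org_id}.bundle.json"
        write_bundle(b, path)
        paths[b.org_id] = path
    write_obo(world.dags["go"], out / "go.obo")
    paths["go"] = out / "go.obo"
    write_class_json(world.dags["compound-class"], out / "compound_classes.json")
    paths["compound-class"] = out / "compound_classes.json"
    write_class_json(world.dags["pathway-class"], out / "pathway_classes.json")
    paths["pathway-class"] = out / "pathway_classes.json"
    with open(out / "hits.tsv", "w", encoding="utf-8") as fh:
        for h in world.hits:
            fh.write(f"{h.query_gene}\t{h.subject_gene}\t{h.e_value:.3g}\n")
    paths["hits"] = out / "hits.tsv"
    save_panel_config(world.panel_tree, out / "panels.json")
    paths["panels"] = out / "panels.json"
    (out / "ledger.json").write_text(
        json.dumps(world.ledger, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    paths["ledger"] = out / "ledger.json"
    return paths
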