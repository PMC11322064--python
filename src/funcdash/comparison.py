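"""Cross-organism analytics.

Overlay statistics decompose each organism's item set for a subsystem into
*common* (present in every organism), *shared* (present in more than one
but not all) and *unique* (present only there) parts -- the numbers behind
the black and white overlay lines on dashboard bar graphs.

Orthologs are designated by reciprocal similarity hits: a gene pair is
accepted iff hits exist in both query directions with both E-values
strictly below the threshold (default 0.001).  Note this is reciprocal hit
*existence*, not reciprocal best hit; the criterion is deliberately the
looser one so that candidate pathway-hole fillers are not missed.

Ortholog-aware comparison pages: for a pathway, which reaction steps have
identified enzymes in which organism, and -- where an organism lacks an
enzyme -- which of its genes are orthologous to the enzymes other
organisms assign to that step (candidate pathway holes).  The analogous
table exists for transporters of a compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from funcdash.core_model import (
    EXPERIMENTAL_EVIDENCE_CODES,
    OrganismBundle,
    Pathway,
)
from funcdash.subsystems import Dashboard, DecoratedNode

DEFAULT_EVALUE_THRESHOLD = 1e-3


# ---------------------------------------------------------------------------
# Common / shared / unique overlays
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlayStats:
    """Per-subsystem common/shared/unique decomposition.

    For every organism ``o``: ``total[o] = common + shared[o] + unique[o]``.
    ``white_bar_omitted`` is true for two-organism comparisons, where every
    non-common item is necessarily unique.
    """

    common_count: int
    totals: dict[str, int]
    shared: dict[str, int]
    unique: dict[str, int]
    white_bar_omitted: bool


def overlay(item_sets: Mapping[str, frozenset | set]) -> OverlayStats:
    """Compute overlay statistics from per-organism item sets (>= 2 sets)."""
    orgs = list(item_sets)
    if len(orgs) < 2:
        raise ValueError("overlay requires item sets for at least two organisms")
    sets = {o: frozenset(item_sets[o]) for o in orgs}
    common_set = frozenset.intersection(*sets.values())
    totals, shared, unique = {}, {}, {}
    for o in orgs:
        others = frozenset().union(*(sets[p] for p in orgs if p != o))
        uniq = sets[o] - others
        totals[o] = len(sets[o])
        unique[o] = len(uniq)
        shared[o] = totals[o] - len(common_set) - unique[o]
    return OverlayStats(
        common_count=len(common_set),
        totals=totals,
        shared=shared,
        unique=unique,
        white_bar_omitted=(len(orgs) == 2),
    )


# ---------------------------------------------------------------------------
# Reciprocal-hit orthologs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HitRecord:
    """One similarity hit (e.g. one row of BLAST/Diamond tabular output)."""

    query_org: str
    query_gene: str
    subject_org: str
    subject_gene: str
    e_value: float

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError(f"negative E-value {self.e_value}")


class OrthologTable:
    """Symmetric set of ortholog gene pairs across organism pairs."""

    def __init__(self, pairs: Iterable[tuple[tuple[str, str], tuple[str, str]]] = ()):
        # each pair: ((org_a, gene_a), (org_b, gene_b)); stored symmetrically
        self._forward: dict[tuple[str, str], set[tuple[str, str]]] = {}
        self._n_pairs = 0
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: tuple[str, str], b: tuple[str, str]) -> None:
        if b not in self._forward.get(a, ()):  # count unordered pairs once
            self._n_pairs += 1
        self._forward.setdefault(a, set()).add(b)
        self._forward.setdefault(b, set()).add(a)

    def __len__(self) -> int:
        return self._n_pairs

    def are_orthologs(self, a: tuple[str, str], b: tuple[str, str]) -> bool:
        return b in self._forward.get(a, ())

    def orthologs_of(self, org: str, gene: str, other_org: str) -> frozenset[str]:
        """Genes of ``other_org`` orthologous to ``(org, gene)``."""
        return frozenset(
            g for (o, g) in self._forward.get((org, gene), ()) if o == other_org
        )

    def pairs(self) -> frozenset[frozenset[tuple[str, str]]]:
        out = set()
        for a, partners in self._forward.items():
            for b in partners:
                out.add(frozenset((a, b)))
        return frozenset(out)


def reciprocal_orthologs(
    hits: Iterable[HitRecord],
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> OrthologTable:
    """Designate orthologs from a hit table by the reciprocal-hit rule.

    ``(g1, g2)`` is an ortholog pair iff a hit g1 -> g2 and a hit g2 -> g1
    both exist with E-value strictly below ``threshold``.  When the same
    directed gene pair appears more than once, the minimum E-value is kept
    before the reciprocity test.  Hits within a single organism are
    ignored.  The result is symmetric and independent of row order.
    """
    if threshold <= 0:
        raise ValueError("E-value threshold must be positive")
    best: dict[tuple[tuple[str, str], tuple[str, str]], float] = {}
    for hit in hits:
        if hit.query_org == hit.subject_org:
            continue
        key = ((hit.query_org, hit.query_gene), (hit.subject_org, hit.subject_gene))
        if key not in best or hit.e_value < best[key]:
            best[key] = hit.e_value
    table = OrthologTable()
    for (a, b), ev in best.items():
        if ev >= threshold:
            continue
        rev = best.get((b, a))
        if rev is not None and rev < threshold:
            table.add(a, b)
    return table


# ---------------------------------------------------------------------------
# Detailed comparison tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrthologSuggestion:
    """A candidate filler for a pathway hole or missing transporter."""

    gene: str  # gene in the organism lacking the assignment
    source_org: str
    source_gene: str  # the assigned enzyme/transporter it is orthologous to


@dataclass
class ReactionCell:
    """Per-(reaction, organism) cell of a pathway comparison table."""

    enzymes: list[tuple[str, str]] = field(default_factory=list)  # (gene, evidence)
    suggestions: list[OrthologSuggestion] = field(default_factory=list)


@dataclass
class PathwayComparisonTable:
    """Reaction-by-reaction comparison of one pathway across organisms.

    ``statuses[(reaction, org)]`` carries the evidence-glyph statuses:
    ``enzyme-identified`` or ``no-enzyme``, plus ``key-step`` and/or
    ``unique-to-pathway`` copied from pathway metadata.  Ortholog
    suggestions appear only in cells with no assigned enzyme.
    """

    pathway_id: str
    pathway_name: str
    organisms: list[str]
    reaction_ids: list[str]
    cells: dict[tuple[str, str], ReactionCell]
    statuses: dict[tuple[str, str], frozenset[str]]
    pathway_flags: dict[str, dict[str, bool]]  # org -> {present, experimental}


def _reference_pathway(bundles: Sequence[OrganismBundle], pathway_id: str) -> Pathway:
    for b in bundles:
        if pathway_id in b.pathways_present:
            return b.pathways_present[pathway_id]
    raise KeyError(f"pathway {pathway_id!r} not present in any bundle")


def pathway_comparison(
    bundles: Sequence[OrganismBundle],
    pathway_id: str,
    orthologs: OrthologTable | None = None,
) -> PathwayComparisonTable:
    """Build the detailed pathway comparison table for one pathway.

    For each reaction step and organism, lists the assigned enzymes with
    their evidence; where no enzyme is assigned, lists genes of that
    organism orthologous to the enzymes other organisms assign to the same
    step -- the enzyme may be present but simply not annotated with that
    function.
    """
    ref = _reference_pathway(bundles, pathway_id)
    orgs = [b.org_id for b in bundles]
    reaction_ids = list(ref.reaction_ids)
    cells: dict[tuple[str, str], ReactionCell] = {}
    statuses: dict[tuple[str, str], frozenset[str]] = {}
    flags: dict[str, dict[str, bool]] = {}

    assigned: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for b in bundles:
        present = pathway_id in b.pathways_present
        pwy = b.pathways_present.get(pathway_id, ref)
        flags[b.org_id] = {
            "present": present,
            "experimental": present and pwy.has_noncomputational_evidence,
        }
        for rid in reaction_ids:
            rxn = b.reactions.get(rid)
            enz = []
            if rxn is not None and present:
                for g in rxn.enzyme_gene_ids:
                    enz.append((g, rxn.enzyme_evidence.get(g, "computational")))
            assigned[(rid, b.org_id)] = enz

    for rid in reaction_ids:
        meta = set()
        if rid in ref.key_reactions:
            meta.add("key-step")
        if rid in ref.unique_reactions:
            meta.add("unique-to-pathway")
        for b in bundles:
            org = b.org_id
            cell = ReactionCell(enzymes=list(assigned[(rid, org)]))
            status = set(meta)
            if cell.enzymes:
                status.add("enzyme-identified")
            else:
                status.add("no-enzyme")
                if orthologs is not None:
                    for other in bundles:
                        if other.org_id == org:
                            continue
                        for src_gene, _ev in assigned[(rid, other.org_id)]:
                            for g in sorted(
                                orthologs.orthologs_of(other.org_id, src_gene, org)
                            ):
                                cell.suggestions.append(
                                    OrthologSuggestion(g, other.org_id, src_gene)
                                )
            cells[(rid, org)] = cell
            statuses[(rid, org)] = frozenset(status)

    return PathwayComparisonTable(
        pathway_id=pathway_id,
        pathway_name=ref.name or pathway_id,
        organisms=orgs,
        reaction_ids=reaction_ids,
        cells=cells,
        statuses=statuses,
        pathway_flags=flags,
    )


@dataclass
class TransporterCell:
    transporters: list[tuple[str, ...]] = field(default_factory=list)
    suggestions: list[OrthologSuggestion] = field(default_factory=list)


def transporter_comparison(
    bundles: Sequence[OrganismBundle],
    compound: str,
    orthologs: OrthologTable | None = None,
) -> dict[str, TransporterCell]:
    """Per-organism transporter inventory for one compound.

    Organisms with no transporter for the compound get ortholog
    suggestions drawn from the other organisms' transporter genes.
    """
    inventory: dict[str, TransporterCell] = {}
    for b in bundles:
        transporters = [
            tuple(t.transporter_gene_ids)
            for t in sorted(b.transport_reactions.values(), key=lambda t: t.id)
            if t.primary_substrate == compound
        ]
        inventory[b.org_id] = TransporterCell(transporters=transporters)
    if orthologs is not None:
        for b in bundles:
            cell = inventory[b.org_id]
            if cell.transporters:
                continue
            for other in bundles:
                if other.org_id == b.org_id:
                    continue
                for t in inventory[other.org_id].transporters:
                    for src_gene in t:
                        for g in sorted(
                            orthologs.orthologs_of(other.org_id, src_gene, b.org_id)
                        ):
                            cell.suggestions.append(
                                OrthologSuggestion(g, other.org_id, src_gene)
                            )
    return inventory


# ---------------------------------------------------------------------------
# Database statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DbStats:
    """Annotation-quality statistics for one organism database."""

    org_id: str
    version: str
    curation_tier: str
    n_genes: int
    n_pathways: int
    n_transport_reactions: int
    n_go_annotations: int
    n_genes_with_molecular_function: int
    n_genes_exp: int
    n_pathways_exp: int
    n_transport_exp: int


def db_stats(bundle: OrganismBundle) -> DbStats:
    """Compute database statistics for one bundle.

    A gene counts as experimentally supported when some reaction assigns
    it with experimental evidence or it carries a GO annotation with an
    experimental evidence code; a pathway when it has non-computational
    evidence; a transport reaction when flagged experimental.
    """
    genes_exp: set[str] = set()
    for rxn in bundle.reactions.values():
        for g, ev in rxn.enzyme_evidence.items():
            if ev == "experimental":
                genes_exp.add(g)
    for ann in bundle.go_annotations:
        if ann.evidence_code in EXPERIMENTAL_EVIDENCE_CODES:
            genes_exp.add(ann.gene_id)
    genes_exp &= set(bundle.genes)
    return DbStats(
        org_id=bundle.org_id,
        version=str(bundle.metadata.get("version", "")),
        curation_tier=str(bundle.metadata.get("curation_tier", "")),
        n_genes=len(bundle.genes),
        n_pathways=len(bundle.pathways_present),
        n_transport_reactions=len(bundle.transport_reactions),
        n_go_annotations=len(bundle.go_annotations),
        n_genes_with_molecular_function=sum(
            1 for g in bundle.genes.values() if g.molecular_function_assigned
        ),
        n_genes_exp=len(genes_exp),
        n_pathways_exp=sum(
            1
            for p in bundle.pathways_present.values()
            if p.has_noncomputational_evidence
        ),
        n_transport_exp=sum(
            1
            for t in bundle.transport_reactions.values()
            if t.evidence == "experimental"
        ),
    )


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchHit:
    """One base panel involving the queried item, with cells to highlight."""

    panel_id: str
    panel_label: str
    matched_cells: tuple[tuple[str, str], ...]  # (row, org) pairs


def _matches(query: str, candidate: str, substring: bool) -> bool:
    q = query.lower()
    c = candidate.lower()
    if q == c:
        return True
    if substring:
        return q in c
    return q in c.split()  # whole-word match on names


def search(
    dashboard: Dashboard,
    query: str,
    substring: bool = False,
) -> list[SearchHit]:
    """Find every base panel involving a compound, GO term, gene or pathway.

    Matching is case-insensitive: exact id match or whole-word name match
    (substring matching behind the ``substring`` flag).  Returns one hit
    per base panel with the matching (row, organism) cells flagged for
    highlighting; an unmatched query yields an empty list.
    """
    hits: list[SearchHit] = []
    for node in dashboard.iter_base():
        if node.omitted or node.tally is None:
            continue
        grid = node.tally.grid
        matched: list[tuple[str, str]] = []
        for row in grid.rows:
            label = grid.row_labels.get(row, row)
            row_match = _matches(query, row, substring) or _matches(
                query, label, substring
            )
            for org in grid.organisms:
                cell = grid.cell(row, org)
                if cell is None:
                    continue
                prov_parts = [
                    part for p in cell.provenance for part in (p, *p.split("+"))
                ]
                if row_match or any(
                    _matches(query, part, substring) for part in prov_parts
                ):
                    matched.append((row, org))
        if matched:
            hits.append(
                SearchHit(
                    panel_id=node.id,
                    panel_label=node.label,
                    matched_cells=tuple(matched),
                )
            )
    return hits
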