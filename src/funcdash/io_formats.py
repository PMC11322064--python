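"""Readers and writers for on-disk formats.

* OBO 1.2/1.4 ontologies (via :mod:`obonet`; ``is_a`` edges only).
* A minimal JSON ontology dialect: ``{"term": ["parent", ...], ...}``.
* GAF 2.1/2.2 gene-association files, merged into a bundle.
* The organism-bundle JSON schema (versioned; documented in
  docs/bundle_schema.md) with canonical, diff-stable serialization.
* Tabular similarity-hit files (BLAST/Diamond outfmt-6 compatible).
* TSV export of comparison grids and pathway-presence tables.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import obonet
import pandas as pd

from funcdash.comparison import HitRecord, PathwayComparisonTable
from funcdash.core_model import (
    GOAnnotation,
    Gene,
    OntologyDAG,
    OntologyError,
    OrganismBundle,
    Pathway,
    Reaction,
    TransportReaction,
)
from funcdash.subsystems import ComparisonGrid

logger = logging.getLogger(__name__)

BUNDLE_SCHEMA_VERSION = 1


class BundleSchemaError(ValueError):
    """A bundle file violates the schema; names the offending JSON pointer."""

    def __init__(self, pointer: str, message: str):
        super().__init__(f"{pointer}: {message}")
        self.pointer = pointer


class HitTableError(ValueError):
    """A similarity-hit table contains malformed rows (line numbers given)."""


# ---------------------------------------------------------------------------
# Ontologies
# ---------------------------------------------------------------------------


def read_obo(path, namespace: str = "go") -> OntologyDAG:
    """Load an OBO 1.2/1.4 file as an :class:`OntologyDAG`.

    Only ``is_a`` edges are used; ``relationship`` edges (part_of,
    regulates, ...) are ignored with a log message.  Obsolete terms are
    skipped with a warning.  A cyclic is-a hierarchy is a load error.
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    parents: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    obsolete: set[str] = set()
    for term, data in graph.nodes(data=True):
        if data.get("is_obsolete") in ("true", True):
            obsolete.add(term)
            logger.warning("OBO %s: skipping obsolete term %s", path, term)
    ignored_rel = 0
    for term, data in graph.nodes(data=True):
        if term in obsolete:
            continue
        parents[term] = set()
        if "name" in data:
            labels[term] = data["name"]
    # obonet edges run child -> parent with the relationship type as key
    for child, parent, rel in graph.edges(keys=True):
        if rel != "is_a":
            ignored_rel += 1
            continue
        if child in obsolete or parent in obsolete:
            continue
        if parent in parents:
            parents[child].add(parent)
    if ignored_rel:
        logger.info(
            "OBO %s: ignored %d non-is_a relationship edges", path, ignored_rel
        )
    return OntologyDAG(parents, labels, namespace=namespace)


def read_class_json(path, namespace: str) -> OntologyDAG:
    """Load a JSON class hierarchy.

    Accepts either a flat ``{"term": ["parent", ...]}`` mapping or the
    structured form ``{"terms": {...}, "labels": {...}}``.
    """
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if "terms" in data and isinstance(data["terms"], dict):
        return OntologyDAG(
            {t: list(ps) for t, ps in data["terms"].items()},
            labels=data.get("labels", {}),
            namespace=namespace,
        )
    if not isinstance(data, dict):
        raise OntologyError(f"{path}: expected a JSON object of term -> parents")
    return OntologyDAG(
        {t: list(ps) for t, ps in data.items()}, namespace=namespace
    )


def write_obo(dag: OntologyDAG, path) -> None:
    """Write a minimal OBO 1.2 file (id / name / is_a stanzas only)."""
    lines = ["format-version: 1.2", f"ontology: {dag.namespace}", ""]
    for term in sorted(dag.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {dag.label(term)}")
        for parent in sorted(dag.parents[term]):
            lines.append(f"is_a: {parent} ! {dag.label(parent)}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def write_class_json(dag: OntologyDAG, path) -> None:
    data = {
        "terms": {t: sorted(ps) for t, ps in sorted(dag.parents.items())},
        "labels": dict(sorted(dag.labels.items())),
    }
    Path(path).write_text(
        json.dumps(data, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# GAF
# ---------------------------------------------------------------------------

_GAF_COLUMNS = 17


def read_gaf(path, bundle: OrganismBundle) -> OrganismBundle:
    """Merge GO annotations from a GAF 2.1/2.2 file into ``bundle``.

    Column 2 (DB object id) is used as the gene key; synonyms are not
    resolved.  The NOT qualifier and the evidence code are preserved.
    Comment lines (``!``) are skipped; a data row with the wrong column
    count is an error naming its line number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("!gaf-version:"):
            raise ValueError(f"{path}: missing !gaf-version header")
        version = first.split(":", 1)[1].strip()
        if not (version.startswith("2.1") or version.startswith("2.2")):
            raise ValueError(f"{path}: unsupported GAF version {version!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) != _GAF_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_GAF_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            gene_id = fields[1]
            qualifier = "NOT" if "NOT" in fields[3].split("|") else "plain"
            term_id = fields[4]
            evidence_code = fields[6]
            bundle.go_annotations.append(
                GOAnnotation(
                    gene_id=gene_id,
                    term_id=term_id,
                    qualifier=qualifier,
                    evidence_code=evidence_code,
                )
            )
            if gene_id not in bundle.genes:
                bundle.genes[gene_id] = Gene(id=gene_id, name=fields[2] or gene_id)
    return bundle


# ---------------------------------------------------------------------------
# Bundle JSON
# ---------------------------------------------------------------------------


def _expect(obj, key: str, typ, pointer: str):
    if key not in obj:
        raise BundleSchemaError(f"{pointer}/{key}", "required field missing")
    value = obj[key]
    if typ is not None and not isinstance(value, typ):
        raise BundleSchemaError(
            f"{pointer}/{key}",
            f"expected {getattr(typ, '__name__', typ)}, got {type(value).__name__}",
        )
    return value


def bundle_to_dict(bundle: OrganismBundle) -> dict:
    """Canonical JSON-ready form: sorted keys and sorted id lists.

    Pathway reaction lists keep their curated order (the order is part of
    the pathway definition); all set-valued id lists are sorted.
    """
    return {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "org_id": bundle.org_id,
        "display_name": bundle.display_name,
        "color": bundle.color,
        "metadata": dict(sorted(bundle.metadata.items())),
        "genes": {
            gid: {
                "name": g.name,
                "product_type": g.product_type,
                "molecular_function_assigned": g.molecular_function_assigned,
            }
            for gid, g in sorted(bundle.genes.items())
        },
        "reactions": {
            rid: {
                "reactants": sorted(r.reactant_ids),
                "products": sorted(r.product_ids),
                "enzymes": {
                    g: r.enzyme_evidence.get(g, "computational")
                    for g in sorted(r.enzyme_gene_ids)
                },
            }
            for rid, r in sorted(bundle.reactions.items())
        },
        "pathways": {
            pid: {
                "name": p.name,
                "class_ids": sorted(p.class_ids),
                "reaction_ids": list(p.reaction_ids),
                "primary_reactants": (
                    sorted(p.primary_reactants)
                    if p.primary_reactants is not None
                    else None
                ),
                "primary_products": (
                    sorted(p.primary_products)
                    if p.primary_products is not None
                    else None
                ),
                "evidence": sorted(p.evidence),
                "base_score": p.base_score,
                "key_reactions": sorted(p.key_reactions),
                "unique_reactions": sorted(p.unique_reactions),
            }
            for pid, p in sorted(bundle.pathways_present.items())
        },
        "transport_reactions": {
            tid: {
                "primary_substrate": t.primary_substrate,
                "transporter_gene_ids": sorted(t.transporter_gene_ids),
                "evidence": t.evidence,
            }
            for tid, t in sorted(bundle.transport_reactions.items())
        },
        "go_annotations": [
            {
                "gene_id": a.gene_id,
                "term_id": a.term_id,
                "qualifier": a.qualifier,
                "evidence_code": a.evidence_code,
            }
            for a in sorted(
                bundle.go_annotations,
                key=lambda a: (a.gene_id, a.term_id, a.qualifier, a.evidence_code),
            )
        ],
    }


def bundle_from_dict(data: Mapping) -> OrganismBundle:
    if not isinstance(data, Mapping):
        raise BundleSchemaError("", "bundle file must be a JSON object")
    version = _expect(data, "schema_version", int, "")
    if version != BUNDLE_SCHEMA_VERSION:
        raise BundleSchemaError(
            "/schema_version",
            f"unsupported version {version} (expected {BUNDLE_SCHEMA_VERSION})",
        )
    org_id = _expect(data, "org_id", str, "")
    genes = {}
    for gid, g in _expect(data, "genes", dict, "").items():
        ptr = f"/genes/{gid}"
        genes[gid] = Gene(
            id=gid,
            name=_expect(g, "name", str, ptr),
            product_type=g.get("product_type", "protein"),
            molecular_function_assigned=bool(
                g.get("molecular_function_assigned", False)
            ),
        )
    reactions = {}
    for rid, r in _expect(data, "reactions", dict, "").items():
        ptr = f"/reactions/{rid}"
        enzymes = _expect(r, "enzymes", dict, ptr)
        reactions[rid] = Reaction(
            id=rid,
            reactant_ids=tuple(_expect(r, "reactants", list, ptr)),
            product_ids=tuple(_expect(r, "products", list, ptr)),
            enzyme_gene_ids=tuple(sorted(enzymes)),
            enzyme_evidence=dict(enzymes),
        )
    pathways = {}
    for pid, p in _expect(data, "pathways", dict, "").items():
        ptr = f"/pathways/{pid}"
        base_score = p.get("base_score")
        if base_score is not None and not isinstance(base_score, (int, float)):
            raise BundleSchemaError(f"{ptr}/base_score", "must be a number or null")
        pathways[pid] = Pathway(
            id=pid,
            name=p.get("name", pid),
            class_ids=tuple(_expect(p, "class_ids", list, ptr)),
            reaction_ids=tuple(_expect(p, "reaction_ids", list, ptr)),
            primary_reactants=(
                tuple(p["primary_reactants"])
                if p.get("primary_reactants") is not None
                else None
            ),
            primary_products=(
                tuple(p["primary_products"])
                if p.get("primary_products") is not None
                else None
            ),
            evidence=frozenset(p.get("evidence", ["computational"])),
            base_score=float(base_score) if base_score is not None else None,
            key_reactions=tuple(p.get("key_reactions", ())),
            unique_reactions=tuple(p.get("unique_reactions", ())),
        )
    transport = {}
    for tid, t in _expect(data, "transport_reactions", dict, "").items():
        ptr = f"/transport_reactions/{tid}"
        transport[tid] = TransportReaction(
            id=tid,
            primary_substrate=_expect(t, "primary_substrate", str, ptr),
            transporter_gene_ids=tuple(
                _expect(t, "transporter_gene_ids", list, ptr)
            ),
            evidence=t.get("evidence", "computational"),
        )
    annotations = []
    for i, a in enumerate(_expect(data, "go_annotations", list, "")):
        ptr = f"/go_annotations/{i}"
        annotations.append(
            GOAnnotation(
                gene_id=_expect(a, "gene_id", str, ptr),
                term_id=_expect(a, "term_id", str, ptr),
                qualifier=a.get("qualifier", "plain"),
                evidence_code=a.get("evidence_code", "IEA"),
            )
        )
    return OrganismBundle(
        org_id=org_id,
        display_name=data.get("display_name") or org_id,
        color=data.get("color"),
        genes=genes,
        reactions=reactions,
        pathways_present=pathways,
        transport_reactions=transport,
        go_annotations=annotations,
        metadata=dict(data.get("metadata", {})),
    )


def read_bundle(path) -> OrganismBundle:
    """Read and schema-validate an organism bundle from JSON."""
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise BundleSchemaError("", f"invalid JSON in {path}: {exc}") from exc
    return bundle_from_dict(data)


def write_bundle(bundle: OrganismBundle, path) -> None:
    """Write a bundle in canonical JSON (stable under round-trips)."""
    Path(path).write_text(
        json.dumps(bundle_to_dict(bundle), indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# Similarity-hit tables
# ---------------------------------------------------------------------------


def read_hit_table(
    path,
    bundles: Sequence[OrganismBundle],
) -> list[HitRecord]:
    """Read a tabular similarity-hit file (outfmt-6 compatible).

    Rows with >= 12 tab-separated columns are treated as full BLAST/Diamond
    tabular output (E-value in column 11); shorter rows as the minimal
    ``qseqid  sseqid  evalue`` form (extra trailing columns ignored).  The
    organism of each gene is resolved via bundle membership; genes found in
    no bundle are skipped with a warning.  Malformed rows are collected and
    reported together with their line numbers.
    """
    gene_org: dict[str, str] = {}
    for b in bundles:
        for gid in b.genes:
            gene_org.setdefault(gid, b.org_id)
    records: list[HitRecord] = []
    bad: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                bad.append(f"line {lineno}: fewer than 3 columns")
                continue
            qseqid, sseqid = fields[0], fields[1]
            raw_ev = fields[10] if len(fields) >= 12 else fields[2]
            try:
                e_value = float(raw_ev)
            except ValueError:
                bad.append(f"line {lineno}: unparseable E-value {raw_ev!r}")
                continue
            if e_value < 0:
                bad.append(f"line {lineno}: negative E-value {e_value}")
                continue
            q_org = gene_org.get(qseqid)
            s_org = gene_org.get(sseqid)
            if q_org is None or s_org is None:
                logger.warning(
                    "%s:%d: gene %r not found in any bundle; row skipped",
                    path,
                    lineno,
                    qseqid if q_org is None else sseqid,
                )
                continue
            records.append(HitRecord(q_org, qseqid, s_org, sseqid, e_value))
    if bad:
        raise HitTableError(f"{path}: malformed rows: " + "; ".join(bad))
    return records


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------


def export_tsv(grid: ComparisonGrid, path) -> None:
    """Write a comparison grid as TSV: one row per item, one column block
    (count, score, provenance) per organism.  Provenance lists are joined
    with commas inside the cell.  Output ordering is deterministic.
    """
    header = ["item", "label"]
    for org in grid.organisms:
        header += [f"{org}:count", f"{org}:score", f"{org}:provenance"]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in grid.rows:
            out = [row, grid.row_labels.get(row, row)]
            for org in grid.organisms:
                cell = grid.cell(row, org)
                if cell is None:
                    out += ["0", "", ""]
                else:
                    out += [
                        str(cell.count),
                        f"{cell.score:g}",
                        ",".join(cell.provenance),
                    ]
            writer.writerow(out)


def read_grid_tsv(path) -> pd.DataFrame:
    """Read a grid TSV back as a DataFrame indexed by item id."""
    return pd.read_csv(path, sep="\t", index_col="item", keep_default_na=False)


def export_presence_tsv(presence: pd.DataFrame, path) -> None:
    """Write a pathway-presence table: one boolean (checkmark-equivalent)
    column per organism, one row per pathway category."""
    out = presence.T  # rows: categories, columns: organisms
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["category"] + list(out.columns))
        for cat, row in out.iterrows():
            writer.writerow([cat] + ["yes" if bool(v) else "no" for v in row])


def export_pathway_comparison_tsv(table: PathwayComparisonTable, path) -> None:
    """Write a detailed pathway comparison table as TSV.

    One row per reaction; per organism a column block with the assigned
    enzymes (evidence in parentheses), the glyph statuses, and any
    ortholog suggestions for empty cells.
    """
    header = ["reaction"]
    for org in table.organisms:
        header += [f"{org}:enzymes", f"{org}:status", f"{org}:suggestions"]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for rid in table.reaction_ids:
            out = [rid]
            for org in table.organisms:
                cell = table.cells[(rid, org)]
                out.append(
                    ",".join(f"{g}({ev})" for g, ev in cell.enzymes)
                )
                out.append(",".join(sorted(table.statuses[(rid, org)])))
                out.append(
                    ",".join(
                        f"{s.gene}<~{s.source_org}:{s.source_gene}"
                        for s in cell.suggestions
                    )
                )
            writer.writerow(out)
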