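# funcdash

**funcdash** builds comparative functional-genomics dashboards: given one
annotation bundle per organism (genes, reactions with enzyme assignments,
pathways with presence evidence, transport reactions, GO annotations) and
three ontologies (a pathway-class hierarchy, a compound-class hierarchy,
and the Gene Ontology), it computes hierarchical comparative functional
profiles and exports them as static HTML dashboards and TSV tables.

It is written for microbiologists and genome curators who want a rapid,
high-level answer to questions like: *which amino acids can each of these
strains synthesize? which metal ions can they transport? which of them
carry sporulation or biofilm genes? and where a pathway step is missing an
enzyme, does the organism have an ortholog of another organism's enzyme
for that step?*

## The model

The dashboard is a hierarchy of panels over *subsystems* of three kinds:

* **Pathway-based** — a subsystem is a triple (pathway class *P*,
  metabolite class *M*, direction *D*). The compound set tallied for
  organism *O* is

  ```
  C = { c : ∃ pathway p present in O, p ∈ closure(P),
            c ∈ primary side D of p, c ∈ closure(M) }
  ```

  where primary reactants/products are curator-designated or inferred as
  the net-terminal compounds of the pathway's reaction list. Every present
  pathway carries a confidence score in [0, 1]:

  ```
  score(p) = 1                                    if p has non-computational evidence
           = max(base_score, |covered| / |rxns|)  otherwise
  ```

  with `covered` the reactions having at least one enzyme identified. The
  per-cell score shown in a grid is the maximum over supporting pathways,
  and it drives box opacity (`0.25 + 0.75·score`).

* **Transport-based** — a compound class *C*; the tally is the set of
  primary substrates of transport reactions falling in *C*, each with its
  transporter inventory. A reserved `OTHER` subsystem collects substrates
  in no configured class.

* **GO-based** — designated GO terms plus an exception list; the tally is
  every gene with a non-NOT annotation to a designated term or its
  descendants, minus the exception closure. Grid rows are the terms genes
  are *directly* annotated to (annotations to child terms do not inflate a
  parent's row).

Parent panels aggregate by set **union**, so a compound produced by two
sibling subsystems counts once. Panels empty in every organism are
omitted. In overlay mode each plot decomposes every bar into
**common** (items in all organisms), **shared** (in ≥ 2 but not all) and
**unique** parts — `total = common + shared + unique`.

Orthologs are designated by **reciprocal similarity hits**: a gene pair is
accepted iff hits exist in both directions with both E-values `< 0.001`.
(This is reciprocal hit *existence*, deliberately looser than classic
reciprocal-best-hit, so candidate pathway-hole fillers are not missed.)

## Worked example

Generate the deterministic six-organism demo world and compare it:

```bash
funcdash make-fixtures --demo --out demo/
cd demo
funcdash compare -b orgA.bundle.json -b orgB.bundle.json -b orgC.bundle.json \
    -b orgD.bundle.json -b orgE.bundle.json -b orgF.bundle.json \
    --go-obo go.obo --compound-classes compound_classes.json \
    --pathway-classes pathway_classes.json --config panels.json \
    --hits hits.tsv --overlay --out site/
# wrote 33 files under site/
```

Open `site/index.html`: one section per panel, one bar plot per
subsystem, drill-down grid pages per base subsystem. The class-1
biosynthesis subsystem of the demo is built with a known overlap
structure, which the engine recovers:

```python
>>> from funcdash.fixtures import make_demo_world
>>> from funcdash.subsystems import build_dashboard
>>> from funcdash.comparison import overlay
>>> w = make_demo_world()
>>> d = build_dashboard(w.bundles, w.panel_tree, w.dags)
>>> n = d.find("bio-1")
>>> n.counts
{'orgA': 8, 'orgB': 6, 'orgC': 7, 'orgD': 7, 'orgE': 7, 'orgF': 7}
>>> s = overlay({o: n.item_sets[o] for o in d.organisms})
>>> s.common_count, s.unique
(5, {'orgA': 1, 'orgB': 1, 'orgC': 1, 'orgD': 1, 'orgE': 1, 'orgF': 1})
```

Five compounds are synthesized by all six organisms; each organism
synthesizes exactly one compound uniquely (organism A also sits in both
"shared" subsets, hence its taller bar). Searching locates an item across
every base panel that involves it:

```
$ funcdash search ... --query C1_0
bio-1        Synthesis class 1    C1_0@orgA, C1_0@orgB, C1_0@orgC, C1_0@orgD, C1_0@orgE, C1_0@orgF
deg-1        Degradation class 1  C1_0@orgB, C1_0@orgC, C1_0@orgE, C1_0@orgF
transport-1  Transport class 1    C1_0@orgA, C1_0@orgB
transport-2  Transport class 2    C1_0@orgA, C1_0@orgB
```

(compound `C1_0` belongs to two compound classes, so it appears under both
transport subsystems). `funcdash stats` prints the database-quality table:

```
org_id  version  curation_tier   n_genes  n_pathways  n_transport_reactions  n_go_annotations  ...
orgA    1.0      curated         191      46          29                     43
orgB    1.1      computational   218      45          29                     75
orgC    1.2      computational   143      47          25                     0
```

## Layout

```
src/funcdash/core_model.py     ontologies, bundles, closures, primary sides
src/funcdash/subsystems.py     subsystem specs, tally engine, panel trees
src/funcdash/comparison.py     overlays, orthologs, comparison tables, search
src/funcdash/io_formats.py     OBO / GAF / bundle JSON / hit tables / TSV
src/funcdash/render_export.py  static site renderer, SVG/PNG export
src/funcdash/fixtures.py       synthetic-world generator with ground-truth ledger
src/funcdash/cli.py            the funcdash command
docs/methods.md                model, assumptions, numerical choices
docs/bundle_schema.md          the organism-bundle JSON schema
docs/panel_config.md           the panel configuration format
```
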