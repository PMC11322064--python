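# Methods

This note documents the computational model behind funcdash, the choices
made where the design was genuinely open, and what the synthetic test
worlds do and do not demonstrate about real data.

## Data model and assumptions

An **organism bundle** stands in for one organism's annotation database:
genes, reactions with per-organism enzyme assignments, pathways asserted
present (with evidence kind and an optional predictor score), transport
reactions with a single primary substrate, and GO annotations. The engine
assumes pathway *presence* is an input: it does not predict pathways, it
only scores and tallies the ones asserted. Likewise similarity hits are
an input table (BLAST/Diamond tabular); funcdash does not run the
aligner.

Ontologies are rooted DAGs of is-a edges. Only `is_a` is honored when
reading OBO; `part_of`, `regulates` and other relationship edges are
ignored (logged), and obsolete terms are dropped with a warning. A cyclic
hierarchy is a hard load error, not a repair — a cycle makes descendant
closures ill-defined, and silently breaking one would bias tallies.

Compounds are modeled as leaves of the compound-class DAG. A compound
unknown to the DAG is a member of no class: it is skipped in pathway
tallies (with a warning, so miscounts are not silent) and lands in the
reserved `OTHER` transport subsystem. A compound under several classes is
tallied under each — the per-panel framing asks "what of class X can this
organism handle", so duplication across panels is correct and parent-level
union aggregation prevents double counting upward.

## Scoring

A pathway with any non-computational evidence record scores exactly 1.0:
curator verification overrides coverage arithmetic. Otherwise the score
is `max(base_score, fraction of reactions with ≥ 1 enzyme)`, with a
missing base score treated as 0. For GO evidence codes, the computational
set defaults to {IEA, ISS, ISA, ISM, ISO} and the experimental set to the
EXP/HTP families; both are module-level constants a caller can override.
Which codes the original curation environments treat as non-computational
is not published, so the lists are deliberately configurable.

Primary reactants/products: curator designations are returned verbatim
when present. The inference rule for undesignated pathways is
**net-terminal**: reactants are compounds consumed by some reaction and
produced by none, products the converse, after removing a configurable
currency-metabolite list (default empty). This is our own choice of
inference rule; it is order-invariant and exact for linear and branched
topologies, but a fully cyclic pathway has no net-terminal compounds and
yields empty sets — such pathways need curator designations.

## Aggregation, ordering, omission

Parent panels aggregate child item sets by **union**, never sum, so one
compound reachable through two child subsystems counts once at the
parent. Grid rows are ordered by descending number of organisms
possessing the item, ties broken alphabetically; all outputs are
deterministic. A node is omitted exactly when every organism's tally
under it is empty. Single-organism mode is the same engine with one
bundle and overlays disabled.

## Overlays and orthologs

Overlay statistics satisfy `total = common + shared + unique` per
organism by construction: common is the size of the global intersection,
unique counts items in no other organism, shared is the remainder. The
white (shared) marker is suppressed for two-organism comparisons, where
non-common implies unique.

Ortholog designation is **reciprocal hit existence** with both E-values
strictly below 0.001 (default): hits in both directions are required, but
neither needs to be the best hit. This is deliberately looser than
classic reciprocal-best-hit and is documented prominently because it
differs from common practice: the consumer of these pairs is the
pathway-hole suggester, where recall matters more than one-to-one
precision. Duplicate directed hits keep their minimum E-value before the
reciprocity test; within-organism hits are ignored. Suggestions appear
only in cells with no assigned enzyme (or no transporter), and each one
names the source organism and source gene it is orthologous to.

## Rendering

The renderer is a pure function of the engine output: every bar embeds
the engine count verbatim (`data-count` attributes in the SVG), and no
tally is recomputed at render time — except overlay statistics, which are
*intentionally* recomputed from the visible organisms, because hiding an
organism changes what "common to all" means. Cell opacity uses the linear
map `0.25 + 0.75·score`: monotone, fully opaque at score 1, with a floor
so a present-but-unsupported capability still renders visibly. The exact
transfer function used by production dashboards is unpublished; this
stand-in satisfies the same visual contract. SVG output is generated
text and byte-deterministic; PNG goes through matplotlib's Agg backend.
Organisms default to alphabetical order by display name and a fixed
12-color colorblind-safe palette, both overridable.

## Synthetic worlds

`fixtures.make_world` generates the entire test universe from one seed:
compound/pathway/GO DAGs, per-organism bundles, hit tables and a matching
panel tree. Default conditions: 4 organisms, 3 compound classes of 8
compounds, up to 30 pathways of 2–5 reactions, pathway presence
probability 0.5, enzyme coverage uniform on [0.3, 1.0], non-computational
evidence on 15% of pathway instances, a predictor base score on 50%, a
24-term GO DAG of depth 3 with ~1.5 annotations per gene, and reciprocal
ortholog pairs over ~30% of genes with distractor one-directional and
above-threshold hits. These sizes keep every property test exhaustive at
sub-second cost while exercising all code paths (multi-class compounds,
diamond-shaped GO terms, NOT annotations, orphan transport substrates).

Crucially the generator records a **ground-truth ledger** — tallies, cell
scores, overlay counts, pathway scores, ortholog pairs — computed by
constructive bookkeeping during generation (its own DFS closures and
membership counts), never by calling the engine. Ledger-vs-engine
agreement is therefore a genuine end-to-end oracle test, and it is
checked across seeds and under organism permutation.

The six-organism demo (`make_demo_world`, or
`funcdash make-fixtures --demo`) adds designed features: a
sporulation-like GO block in exactly one organism, an exclusive
photosynthesis-like energy category, one GO-less organism, one
compound-class-poor organism, and a subsystem with exactly five common
plus per-organism unique compounds for the overlay display. The demo is
fully deterministic and regenerated on demand rather than stored.

What the synthetic worlds do *not* emulate: real pathway content and
topology (no cyclic pathways, no shared reactions between pathways),
realistic GO term depth or annotation bias, gene synonymy, or E-value
distributions of real aligners. Passing tests demonstrate the
correctness of the set/closure/scoring arithmetic and the plumbing, not
the biological plausibility of any particular comparison — on real data,
results remain as sensitive to annotation quality and pathway-prediction
quality as the underlying databases are.

## Numerical and degenerate-input choices

* Scores and E-values are plain floats; score comparisons in tests use
  exact or 1e-12 tolerances since the arithmetic is rational.
* A pathway with zero reactions has an undefined coverage fraction:
  scoring raises, and primary-side inference raises unless designations
  exist.
* Bundle JSON is written canonically (sorted keys, sorted set-valued id
  lists) so diffs are stable; pathway reaction lists keep curated order,
  which is part of the pathway definition.
* GAF column 2 (DB object id) is the gene key; synonyms are not
  resolved — determinism over recall.
* Hit-table rows with ≥ 12 columns are treated as full outfmt-6 (E-value
  in column 11), shorter rows as minimal `query, subject, evalue`.
* Search matches case-insensitive exact ids or whole words of display
  names; substring matching is opt-in to keep default results precise.

## Known limitations

* No reasoning over non-is_a ontology edges and no OWL.
* Pathway diagrams are not drawn; pathway detail is exported as tables.
* The shipped default panel configuration covers the documented example
  subsystems only; real deployments are expected to edit it (the full
  subsystem catalogs of production systems are not published).
* The operon-organization row of detailed pathway comparisons is not
  implemented.
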