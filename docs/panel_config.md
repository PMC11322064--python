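# Panel configuration format (version 1)

The panel tree is a versioned JSON document; the shipped default lives at
`src/funcdash/data/default_panels.json` and is meant to be copied and
edited. Top-level structure:

```json
{
  "config_version": 1,
  "panels": [ <node>, ... ]
}
```

A **node** is either an inner panel with `children` or a base panel with
a `subsystem`:

```json
{"id": "biosynthesis", "label": "Biosynthesis", "children": [ <node>, ... ]}

{"id": "amino-acid-syn", "label": "Amino Acid Syn",
 "subsystem": { ...kind-specific fields... }}
```

Subsystem kinds and their fields:

* `"kind": "pathway"` — `pathway_class` (pathway-ontology term),
  `metabolite_class` (compound-ontology term), `direction`
  (`"outputs"` for biosynthesis families, `"inputs"` for degradation
  families).
* `"kind": "transport"` — `compound_class` (compound-ontology term, or
  the reserved string `"OTHER"` for substrates matching no configured
  class).
* `"kind": "go"` — `term_ids` (≥ 1 GO ids), optional
  `exception_term_ids` whose descendant closures are excluded.
* `"kind": "pathway-presence-matrix"` — `categories`: pathway-class ids
  (closure applies, so any variant counts) or concrete pathway ids; the
  subsystem renders a boolean presence grid instead of compound counts.

Ids must be unique across the tree; `label` defaults to `id`. Unknown
ontology terms referenced by a subsystem raise a configuration error at
build time (CLI exit code 2). `funcdash.subsystems.load_panel_config` /
`save_panel_config` round-trip this format.
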