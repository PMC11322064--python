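# Organism bundle JSON schema (version 1)

One file per organism. Readers validate structurally and report
violations with JSON-pointer loci (e.g. `/reactions/r1/enzymes`). Writers
emit canonical form: sorted object keys, sorted set-valued id lists;
`pathways/*/reaction_ids` keeps its curated order.

```json
{
  "schema_version": 1,
  "org_id": "orgA",
  "display_name": "Synthetic organism A",
  "color": "#332288",
  "metadata": {"version": "1.0", "curation_tier": "curated"},
  "genes": {
    "g1": {
      "name": "argA",
      "product_type": "protein",
      "molecular_function_assigned": true
    }
  },
  "reactions": {
    "r1": {
      "reactants": ["pre"],
      "products": ["mid"],
      "enzymes": {"g1": "experimental"}
    }
  },
  "pathways": {
    "ARG-PWY": {
      "name": "arginine biosynthesis",
      "class_ids": ["AA-Biosynthesis"],
      "reaction_ids": ["r1", "r2"],
      "primary_reactants": ["pre"],
      "primary_products": ["arg"],
      "evidence": ["computational", "non-computational"],
      "base_score": 0.85,
      "key_reactions": ["r2"],
      "unique_reactions": []
    }
  },
  "transport_reactions": {
    "T1": {
      "primary_substrate": "arg",
      "transporter_gene_ids": ["zt1"],
      "evidence": "computational"
    }
  },
  "go_annotations": [
    {
      "gene_id": "g1",
      "term_id": "GO:0006351",
      "qualifier": "plain",
      "evidence_code": "IDA"
    }
  ]
}
```

Field notes:

| Field | Required | Meaning |
| --- | --- | --- |
| `schema_version` | yes | must equal `1` |
| `org_id` | yes | unique within a comparison set |
| `display_name`, `color` | no | render hints (`color` is hex) |
| `metadata.version`, `metadata.curation_tier` | no | provenance shown in the statistics table |
| `genes.*.molecular_function_assigned` | no (default false) | counts toward the statistics table |
| `reactions.*.enzymes` | yes (may be empty) | gene id → `"experimental"` or `"computational"` |
| `pathways.*.evidence` | no (default `["computational"]`) | `"non-computational"` forces score 1.0 |
| `pathways.*.base_score` | no | predictor confidence in [0, 1], or null |
| `pathways.*.primary_reactants/products` | no | null means "infer net-terminal" |
| `pathways.*.key_reactions`, `unique_reactions` | no | subsets of `reaction_ids`; drive evidence glyphs |
| `transport_reactions.*.transporter_gene_ids` | yes, non-empty | a complex lists several genes |
| `go_annotations.*.qualifier` | no (default `"plain"`) | `"NOT"` excludes the annotation from all gene sets |

GO annotations can also be merged from GAF 2.1/2.2 files
(`funcdash.io_formats.read_gaf`); GAF column 2 is the gene key.
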