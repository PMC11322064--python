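{
  "config_version": 1,
  "description": "Default dashboard panel layout. Pathway/metabolite class ids follow MetaCyc ontology naming; GO subsystems list the documented example terms and are meant to be extended by the user. See docs/panel_config.md.",
  "panels": [
    {
      "id": "biosynthesis",
      "label": "Biosynthesis",
      "children": [
        {"id": "amino-acid-syn", "label": "Amino Acid Syn",
         "subsystem": {"kind": "pathway", "pathway_class": "Amino-Acid-Biosynthesis", "metabolite_class": "Amino-Acids", "direction": "outputs"}},
        {"id": "carbohydrate-syn", "label": "Carbohydrates Syn",
         "subsystem": {"kind": "pathway", "pathway_class": "Carbohydrates-Biosynthesis", "metabolite_class": "Carbohydrates", "direction": "outputs"}},
        {"id": "cofactor-syn", "label": "Cofactor Syn",
         "subsystem": {"kind": "pathway", "pathway_class": "Cofactor-Biosynthesis", "metabolite_class": "Cofactors", "direction": "outputs"}},
        {"id": "nucleotide-syn", "label": "Nucleotide Syn",
         "subsystem": {"kind": "pathway", "pathway_class": "Nucleotide-Biosynthesis", "metabolite_class": "Nucleotides", "direction": "outputs"}},
        {"id": "lipid-syn", "label": "Lipid Syn",
         "subsystem": {"kind": "pathway", "pathway_class": "Lipid-Biosynthesis", "metabolite_class": "Lipids", "direction": "outputs"}}
      ]
    },
    {
      "id": "degradation",
      "label": "Degradation/Utilization/Assimilation",
      "children": [
        {"id": "amino-acid-deg", "label": "Amino Acid Deg",
         "subsystem": {"kind": "pathway", "pathway_class": "Amino-Acid-Degradation", "metabolite_class": "Amino-Acids", "direction": "inputs"}},
        {"id": "carbohydrate-deg", "label": "Carbohydrates Deg",
         "subsystem": {"kind": "pathway", "pathway_class": "Carbohydrates-Degradation", "metabolite_class": "Carbohydrates", "direction": "inputs"}},
        {"id": "aromatic-deg", "label": "Aromatic Cpd Deg",
         "subsystem": {"kind": "pathway", "pathway_class": "Aromatic-Compounds-Degradation", "metabolite_class": "Aromatic-Compounds", "direction": "inputs"}},
        {"id": "amine-deg", "label": "Amine Deg",
         "subsystem": {"kind": "pathway", "pathway_class": "Amine-Degradation", "metabolite_class": "Amines", "direction": "inputs"}}
      ]
    },
    {
      "id": "energy",
      "label": "Energy Metabolism/Precursor Metabolites",
      "children": [
        {"id": "fermentation", "label": "Fermentation",
         "subsystem": {"kind": "pathway", "pathway_class": "Fermentation", "metabolite_class": "Carbohydrates", "direction": "inputs"}},
        {"id": "energy-categories", "label": "Energy Pathway Categories",
         "subsystem": {"kind": "pathway-presence-matrix",
                       "categories": ["TCA-Cycle", "Photosynthesis", "Glycolysis", "Pentose-Phosphate-Cycle", "Respiration"]}}
      ]
    },
    {
      "id": "transport",
      "label": "Transport",
      "children": [
        {"id": "transport-inorganic-ions", "label": "Inorganic Ions",
         "subsystem": {"kind": "transport", "compound_class": "Inorganic-Ions"}},
        {"id": "transport-carbohydrates", "label": "Carbohydrates",
         "subsystem": {"kind": "transport", "compound_class": "Carbohydrates"}},
        {"id": "transport-amino-acids", "label": "Amino Acids",
         "subsystem": {"kind": "transport", "compound_class": "Amino-Acids"}},
        {"id": "transport-other", "label": "Other",
         "subsystem": {"kind": "transport", "compound_class": "OTHER"}}
      ]
    },
    {
      "id": "central-dogma",
      "label": "Central Dogma",
      "children": [
        {"id": "transcription", "label": "Transcription",
         "subsystem": {"kind": "go", "term_ids": ["GO:0006351"]}},
        {"id": "translation", "label": "Translation",
         "subsystem": {"kind": "go", "term_ids": ["GO:0006412"]}},
        {"id": "dna-metabolism", "label": "DNA Metabolism",
         "subsystem": {"kind": "go", "term_ids": ["GO:0006259"]}},
        {"id": "protein-folding", "label": "Protein Folding",
         "subsystem": {"kind": "go", "term_ids": ["GO:0006457"]}}
      ]
    },
    {
      "id": "response-to-stimulus",
      "label": "Response to Stimulus",
      "children": [
        {"id": "dna-damage-response", "label": "DNA Damage Response",
         "subsystem": {"kind": "go", "term_ids": ["GO:0006974"]}},
        {"id": "stress-response", "label": "Stress Response",
         "subsystem": {"kind": "go", "term_ids": ["GO:0033554"]}}
      ]
    },
    {
      "id": "cellular-processes",
      "label": "Cellular Processes",
      "children": [
        {"id": "sporulation", "label": "Sporulation",
         "subsystem": {"kind": "go", "term_ids": ["GO:0030435"]}},
        {"id": "biofilm-formation", "label": "Biofilm Formation",
         "subsystem": {"kind": "go", "term_ids": ["GO:0042710"]}},
        {"id": "cell-cycle", "label": "Cell Cycle",
         "subsystem": {"kind": "go", "term_ids": ["GO:0007049"]}}
      ]
    },
    {
      "id": "virulence",
      "label": "Virulence-Related",
      "children": [
        {"id": "movement-in-host", "label": "Movement in Host",
         "subsystem": {"kind": "go", "term_ids": ["GO:0044001", "GO:0044409", "GO:0035891"]}},
        {"id": "other-host-interaction", "label": "Other Host Interaction",
         "subsystem": {"kind": "go", "term_ids": ["GO:0051701"],
                       "exception_term_ids": ["GO:0044001", "GO:0044409", "GO:0035891"]}},
        {"id": "locomotion", "label": "Locomotion",
         "subsystem": {"kind": "go", "term_ids": ["GO:0040011"]}},
        {"id": "protein-secretion", "label": "Protein Secretion",
         "subsystem": {"kind": "go", "term_ids": ["GO:0009306"]}}
      ]
    },
    {
      "id": "cell-exterior",
      "label": "Cell Exterior",
      "children": [
        {"id": "cell-wall", "label": "Cell Wall",
         "subsystem": {"kind": "go", "term_ids": ["GO:0005618"]}},
        {"id": "outer-membrane", "label": "Outer Membrane",
         "subsystem": {"kind": "go", "term_ids": ["GO:0019867"]}}
      ]
    }
  ]
}
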