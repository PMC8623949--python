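{
  "seed": 7,
  "genes_per_locus": 12,
  "gene_length": [
    500,
    1200
  ],
  "intergenic_length": [
    600,
    1200
  ],
  "n_markers": 10,
  "marker_length": [
    100,
    160
  ],
  "flank_length": 1500,
  "genomes": [
    {
      "name": "svevo",
      "species_class": "wheat",
      "divergence": 0.0
    },
    {
      "name": "zavitan",
      "species_class": "wheat",
      "divergence": 0.01
    },
    {
      "name": "barley",
      "species_class": "barley_rye",
      "divergence": 0.05
    },
    {
      "name": "rice",
      "species_class": "rice",
      "divergence": 0.12
    }
  ],
  "structural_events": [
    {
      "genome": "barley",
      "kind": "inversion",
      "gene_start": 3,
      "n_genes": 6
    }
  ],
  "mirna_plantings": [
    {
      "family": "miR9001"
    },
    {
      "family": "miR9002",
      "violate": "duplex"
    }
  ]
}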