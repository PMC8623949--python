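{
  "locus_name": "synthetic-3BL",
  "genomes": [
    {
      "name": "svevo",
      "genome_fasta": "demo/fixture/svevo.genome.fasta",
      "gff3": "demo/fixture/svevo.gff3",
      "cds_fasta": "demo/fixture/svevo.cds.fasta",
      "species_class": "wheat"
    },
    {
      "name": "zavitan",
      "genome_fasta": "demo/fixture/zavitan.genome.fasta",
      "gff3": "demo/fixture/zavitan.gff3",
      "cds_fasta": "demo/fixture/zavitan.cds.fasta",
      "species_class": "wheat"
    },
    {
      "name": "barley",
      "genome_fasta": "demo/fixture/barley.genome.fasta",
      "gff3": "demo/fixture/barley.gff3",
      "cds_fasta": "demo/fixture/barley.cds.fasta",
      "species_class": "barley_rye"
    },
    {
      "name": "rice",
      "genome_fasta": "demo/fixture/rice.genome.fasta",
      "gff3": "demo/fixture/rice.gff3",
      "cds_fasta": "demo/fixture/rice.cds.fasta",
      "species_class": "rice"
    }
  ],
  "reference": "svevo",
  "markers_fasta": "demo/fixture/markers.fasta",
  "matures_fasta": "demo/fixture/matures.fasta",
  "outdir": "demo/run",
  "seed": 7
}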