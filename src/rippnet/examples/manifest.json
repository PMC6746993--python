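{
  "example": {
    "files": {
      "example.neg.fasta": "d8c8b56a0283d3e2c7e6c57ddaef751800156b862c5827352a98b8fbad142fba",
      "example.pos.fasta": "04098c3149c27294f13f9419372491166d683d3b0b406fb389f4c06ab096817d"
    },
    "params": {
      "description": "40 motif-bearing positives and 80 composition-matched negatives",
      "n_positive": 40,
      "ratio": 2,
      "seed": 2019,
      "substitution_prob": 0.1
    }
  }
}
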