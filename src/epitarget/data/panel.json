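{
  "coordinate_system": "hg19, 1-based, inclusive",
  "amplicons": [
    {
      "locus_id": "1.1",
      "primer_f": "GGGGGTTAAAGTTTGAATGTTTATTA",
      "primer_r": "AAAAAAAATTCCTATCCCAAAAAAT",
      "insert_chrom": "chr6",
      "insert_start": 10555691,
      "insert_end": 10555946,
      "encompassed_cpgs": [10555808, 10555853, 10555881, 10555905],
      "merged_pairs": []
    },
    {
      "locus_id": "1.2",
      "primer_f": "TTTTTATTTGAGATGTTATTTGTGTTA",
      "primer_r": "CCCCCTAATTACTACCATTCAAAA",
      "insert_chrom": "chr6",
      "insert_start": 10556024,
      "insert_end": 10556275,
      "encompassed_cpgs": [10556052, 10556069, 10556098, 10556107, 10556147, 10556174, 10556199, 10556204, 10556244],
      "merged_pairs": [[10556107, 10556147], [10556199, 10556204]]
    },
    {
      "locus_id": "2.1",
      "primer_f": "TGGGTTTGTTTTTGTTAGATGATAG",
      "primer_r": "AACCCACAACAACTTACTCTCCTAA",
      "insert_chrom": "chr2",
      "insert_start": 206628380,
      "insert_end": 206628588,
      "encompassed_cpgs": [206628415, 206628454, 206628484, 206628491, 206628521, 206628525, 206628529, 206628531, 206628539, 206628553],
      "merged_pairs": [[206628521, 206628525], [206628529, 206628531]]
    },
    {
      "locus_id": "2.2",
      "primer_f": "GGAGAGTAAGTTGTTGTGGGTTATT",
      "primer_r": "TAACAAATAAAAATATCATTCAATTACCAT",
      "insert_chrom": "chr2",
      "insert_start": 206628567,
      "insert_end": 206628809,
      "encompassed_cpgs": [206628592, 206628606, 206628609, 206628621, 206628625, 206628645, 206628692, 206628714, 206628727, 206628737, 206628747, 206628773],
      "merged_pairs": [[206628645, 206628692], [206628727, 206628737]]
    }
  ]
}
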