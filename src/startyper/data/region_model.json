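{
 "GRCh38": {
  "chrom": "chr22",
  "d6_span": [
   42126499,
   42130810
  ],
  "d7_span": [
   42139677,
   42143988
  ],
  "rep6_span": [
   42123192,
   42125972
  ],
  "rep7_span": [
   42135344,
   42138124
  ],
  "spacer_span": [
   42138124,
   42139676
  ],
  "d6_exons": {
   "1": [
    42130481,
    42130810
   ],
   "2": [
    42129691,
    42129861
   ],
   "3": [
    42129031,
    42129211
   ],
   "4": [
    42128801,
    42128981
   ],
   "5": [
    42128191,
    42128361
   ],
   "6": [
    42127881,
    42128061
   ],
   "7": [
    42127401,
    42127561
   ],
   "8": [
    42126921,
    42127061
   ],
   "9": [
    42126561,
    42126761
   ]
  },
  "d7_exons": {
   "1": [
    42143659,
    42143988
   ],
   "2": [
    42142869,
    42143039
   ],
   "3": [
    42142209,
    42142389
   ],
   "4": [
    42141979,
    42142159
   ],
   "5": [
    42141369,
    42141539
   ],
   "6": [
    42141059,
    42141239
   ],
   "7": [
    42140579,
    42140739
   ],
   "8": [
    42140099,
    42140239
   ],
   "9": [
    42139739,
    42139939
   ]
  },
  "homology_regions": [
   [
    42129711,
    42130810
   ],
   [
    42126499,
    42128011
   ]
  ]
 },
 "GRCh37": {
  "chrom": "22",
  "d6_span": [
   42522501,
   42526812
  ],
  "d7_span": [
   42535679,
   42539990
  ],
  "rep6_span": [
   42519194,
   42521974
  ],
  "rep7_span": [
   42531346,
   42534126
  ],
  "spacer_span": [
   42534126,
   42535678
  ],
  "d6_exons": {
   "1": [
    42526483,
    42526812
   ],
   "2": [
    42525693,
    42525863
   ],
   "3": [
    42525033,
    42525213
   ],
   "4": [
    42524803,
    42524983
   ],
   "5": [
    42524193,
    42524363
   ],
   "6": [
    42523883,
    42524063
   ],
   "7": [
    42523403,
    42523563
   ],
   "8": [
    42522923,
    42523063
   ],
   "9": [
    42522563,
    42522763
   ]
  },
  "d7_exons": {
   "1": [
    42539661,
    42539990
   ],
   "2": [
    42538871,
    42539041
   ],
   "3": [
    42538211,
    42538391
   ],
   "4": [
    42537981,
    42538161
   ],
   "5": [
    42537371,
    42537541
   ],
   "6": [
    42537061,
    42537241
   ],
   "7": [
    42536581,
    42536741
   ],
   "8": [
    42536101,
    42536241
   ],
   "9": [
    42535741,
    42535941
   ]
  },
  "homology_regions": [
   [
    42525713,
    42526812
   ],
   [
    42522501,
    42524013
   ]
  ]
 }
}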