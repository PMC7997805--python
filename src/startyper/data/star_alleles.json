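{
 "alleles": [
  {
   "name": "*1",
   "variants": [],
   "sv": "none",
   "activity_score": 1.0,
   "function": "normal",
   "validated": true
  },
  {
   "name": "*2",
   "variants": [
    "g.2851C>T",
    "g.4181G>C"
   ],
   "sv": "none",
   "activity_score": 1.0,
   "function": "normal",
   "validated": true
  },
  {
   "name": "*3",
   "variants": [
    "g.2549delA"
   ],
   "sv": "none",
   "activity_score": 0.0,
   "function": "no",
   "validated": true
  },
  {
   "name": "*4",
   "variants": [
    "g.100C>T",
    "g.1847G>A",
    "g.4181G>C"
   ],
   "sv": "none",
   "activity_score": 0.0,
   "function": "no",
   "validated": true
  },
  {
   "name": "*5",
   "variants": [],
   "sv": "deletion",
   "activity_score": 0.0,
   "function": "no",
   "validated": true
  },
  {
   "name": "*6",
   "variants": [
    "g.1708delT"
   ],
   "sv": "none",
   "activity_score": 0.0,
   "function": "no",
   "validated": true
  },
  {
   "name": "*7",
   "variants": [
    "g.2853A>C"
   ],
   "sv": "none",
   "activity_score": 0.0,
   "function": "no",
   "validated": true
  },
  {
   "name": "*9",
   "variants": [
    "g.2615_2617delAAG"
   ],
   "sv": "none",
   "activity_score": 0.5,
   "function": "decreased",
   "validated": true
  },
  {
   "name": "*10",
   "variants": [
    "g.100C>T",
    "g.4181G>C"
   ],
   "sv": "none",
   "activity_score": 0.25,
   "function": "decreased",
   "validated": true
  },
  {
   "name": "*11",
   "variants": [
    "g.883G>C"
   ],
   "sv": "none",
   "activity_score": 0.0,
   "function": "no",
   "validated": true
  },
  {
   "name": "*13",
   "variants": [],
   "sv": {
    "type": "d7_d6",
    "d6_from_exon": 2,
    "fused": true
   },
   "activity_score": 0.0,
   "function": "no",
   "validated": true
  },
  {
   "name": "*14",
   "variants": [
    "g.1758G>A"
   ],
   "sv": "none",
   "activity_score": 0.5,
   "function": "decreased",
   "validated": true
  },
  {
   "name": "*15",
   "variants": [
    "g.137_138insT"
   ],
   "sv": "none",
   "activity_score": 0.0,
   "function": "no",
   "validated": true
  },
  {
   "name": "*17",
   "variants": [
    "g.1022C>T",
    "g.2851C>T",
    "g.4181G>C"
   ],
   "sv": "none",
   "activity_score": 0.5,
   "function": "decreased",
   "validated": true
  },
  {
   "name": "*21",
   "variants": [
    "g.2573_2574insC"
   ],
   "sv": "none",
   "activity_score": 0.0,
   "function": "no",
   "validated": true
  },
  {
   "name": "*22",
   "variants": [
    "g.82C>T"
   ],
   "sv": "none",
   "activity_score": null,
   "function": "uncertain",
   "validated": true
  },
  {
   "name": "*28",
   "variants": [
    "g.19G>A"
   ],
   "sv": "none",
   "activity_score": null,
   "function": "uncertain",
   "validated": true
  },
  {
   "name": "*29",
   "variants": [
    "g.1659G>A",
    "g.3183G>A"
   ],
   "sv": "none",
   "activity_score": 0.5,
   "function": "decreased",
   "validated": true
  },
  {
   "name": "*31",
   "variants": [
    "g.4043G>A"
   ],
   "sv": "none",
   "activity_score": 0.0,
   "function": "no",
   "validated": true
  },
  {
   "name": "*33",
   "variants": [
    "g.2483G>T"
   ],
   "sv": "none",
   "activity_score": 1.0,
   "function": "normal",
   "validated": true
  },
  {
   "name": "*35",
   "variants": [
    "g.31G>A",
    "g.2851C>T",
    "g.4181G>C"
   ],
   "sv": "none",
   "activity_score": 1.0,
   "function": "normal",
   "validated": true
  },
  {
   "name": "*36",
   "variants": [
    "g.100C>T"
   ],
   "sv": {
    "type": "d6_d7",
    "d6_through_exon": 8
   },
   "activity_score": 0.0,
   "function": "no",
   "validated": false
  },
  {
   "name": "*39",
   "variants": [
    "g.4181G>C"
   ],
   "sv": "none",
   "activity_score": 1.0,
   "function": "normal",
   "validated": true
  },
  {
   "name": "*40",
   "variants": [
    "g.1863_1864insTTTCGCCCC"
   ],
   "sv": "none",
   "activity_score": 0.0,
   "function": "no",
   "validated": true
  },
  {
   "name": "*41",
   "variants": [
    "g.2989G>A"
   ],
   "sv": "none",
   "activity_score": 0.25,
   "function": "decreased",
   "validated": true
  },
  {
   "name": "*43",
   "variants": [
    "g.77G>A"
   ],
   "sv": "none",
   "activity_score": null,
   "function": "uncertain",
   "validated": true
  },
  {
   "name": "*45",
   "variants": [
    "g.2129A>C"
   ],
   "sv": "none",
   "activity_score": 1.0,
   "function": "normal",
   "validated": true
  },
  {
   "name": "*46",
   "variants": [
    "g.1716G>A"
   ],
   "sv": "none",
   "activity_score": 1.0,
   "function": "normal",
   "validated": true
  },
  {
   "name": "*49",
   "variants": [
    "g.1612T>A"
   ],
   "sv": "none",
   "activity_score": 0.5,
   "function": "decreased",
   "validated": true
  },
  {
   "name": "*52",
   "variants": [
    "g.4115C>T"
   ],
   "sv": "none",
   "activity_score": null,
   "function": "uncertain",
   "validated": true
  },
  {
   "name": "*56",
   "variants": [
    "g.3201C>T"
   ],
   "sv": "none",
   "activity_score": 0.0,
   "function": "no",
   "validated": true
  },
  {
   "name": "*59",
   "variants": [
    "g.2939G>A"
   ],
   "sv": "none",
   "activity_score": 0.5,
   "function": "decreased",
   "validated": true
  },
  {
   "name": "*68",
   "variants": [
    "g.100C>T"
   ],
   "sv": {
    "type": "d6_d7",
    "d6_through_exon": 1
   },
   "activity_score": 0.0,
   "function": "no",
   "validated": true
  },
  {
   "name": "*71",
   "variants": [
    "g.125G>A"
   ],
   "sv": "none",
   "activity_score": null,
   "function": "uncertain",
   "validated": true
  },
  {
   "name": "*82",
   "variants": [
    "g.2312G>A"
   ],
   "sv": "none",
   "activity_score": null,
   "function": "unknown",
   "validated": true
  },
  {
   "name": "*83",
   "variants": [],
   "sv": {
    "type": "d6_d7",
    "d6_through_exon": 4
   },
   "activity_score": null,
   "function": "uncertain",
   "validated": true
  },
  {
   "name": "*84",
   "variants": [
    "g.4242G>A"
   ],
   "sv": "none",
   "activity_score": null,
   "function": "uncertain",
   "validated": false
  },
  {
   "name": "*86",
   "variants": [
    "g.4042G>A"
   ],
   "sv": "none",
   "activity_score": null,
   "function": "unknown",
   "validated": false
  },
  {
   "name": "*90",
   "variants": [
    "g.218G>A"
   ],
   "sv": "none",
   "activity_score": null,
   "function": "uncertain",
   "validated": false
  },
  {
   "name": "*99",
   "variants": [
    "g.3254T>C"
   ],
   "sv": "none",
   "activity_score": 0.0,
   "function": "no",
   "validated": true
  },
  {
   "name": "*106",
   "variants": [
    "g.3277T>C"
   ],
   "sv": "none",
   "activity_score": null,
   "function": "uncertain",
   "validated": true
  },
  {
   "name": "*108",
   "variants": [
    "g.1897C>T"
   ],
   "sv": "none",
   "activity_score": null,
   "function": "unknown",
   "validated": false
  },
  {
   "name": "*111",
   "variants": [
    "g.1757C>T"
   ],
   "sv": "none",
   "activity_score": null,
   "function": "unknown",
   "validated": true
  },
  {
   "name": "*112",
   "variants": [
    "g.3387C>T"
   ],
   "sv": "none",
   "activity_score": null,
   "function": "unknown",
   "validated": true
  },
  {
   "name": "*113",
   "variants": [
    "g.7A>G"
   ],
   "sv": "none",
   "activity_score": null,
   "function": "unknown",
   "validated": true
  },
  {
   "name": "*4.013",
   "variants": [
    "g.1847G>A",
    "g.4181G>C"
   ],
   "sv": {
    "type": "d7_d6",
    "d6_from_exon": 2,
    "fused": false
   },
   "activity_score": 0.0,
   "function": "no",
   "validated": false
  }
 ],
 "tandems": [
  [
   "*68",
   "*4"
  ],
  [
   "*68",
   "*68",
   "*4"
  ],
  [
   "*36",
   "*10"
  ],
  [
   "*36",
   "*36",
   "*10"
  ],
  [
   "*36",
   "*36",
   "*36",
   "*10"
  ],
  [
   "*36",
   "*36",
   "*83",
   "*10"
  ],
  [
   "*13",
   "*2"
  ],
  [
   "*4.013",
   "*4"
  ],
  [
   "*1",
   "*90"
  ]
 ],
 "provenance": "synthetic curated definition table (PharmVar-style schema)"
}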