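{
 "promoter": "U1",
 "subunit": "SNAP190",
 "protein_length": 721,
 "assignments": {
  "3": {
   "phosphate_index": 3,
   "strand": "non_template",
   "promoter": "U1",
   "protein_length": 721,
   "intervals": [
    {
     "lo": 410,
     "hi": 483,
     "grade": "strong",
     "certainty": "exact"
    }
   ],
   "ambiguous": [],
   "excluded": [
    [
     1,
     409
    ],
    [
     484,
     721
    ]
   ],
   "untested": [],
   "conflicts": [],
   "warnings": [],
   "notes": {}
  },
  "5": {
   "phosphate_index": 5,
   "strand": "non_template",
   "promoter": "U1",
   "protein_length": 721,
   "intervals": [
    {
     "lo": 306,
     "hi": 358,
     "grade": "strong",
     "certainty": "exact"
    }
   ],
   "ambiguous": [],
   "excluded": [
    [
     1,
     305
    ],
    [
     359,
     721
    ]
   ],
   "untested": [],
   "conflicts": [],
   "warnings": [],
   "notes": {}
  },
  "7": {
   "phosphate_index": 7,
   "strand": "non_template",
   "promoter": "U1",
   "protein_length": 721,
   "intervals": [
    {
     "lo": 248,
     "hi": 305,
     "grade": "strong",
     "certainty": "exact"
    },
    {
     "lo": 306,
     "hi": 358,
     "grade": "weak",
     "certainty": "exact"
    }
   ],
   "ambiguous": [],
   "excluded": [
    [
     1,
     247
    ],
    [
     359,
     721
    ]
   ],
   "untested": [],
   "conflicts": [],
   "warnings": [],
   "notes": {}
  },
  "8": {
   "phosphate_index": 8,
   "strand": "template",
   "promoter": "U1",
   "protein_length": 721,
   "intervals": [
    {
     "lo": 359,
     "hi": 409,
     "grade": "strong",
     "certainty": "exact"
    }
   ],
   "ambiguous": [],
   "excluded": [
    [
     1,
     358
    ],
    [
     410,
     721
    ]
   ],
   "untested": [],
   "conflicts": [],
   "warnings": [],
   "notes": {}
  },
  "10": {
   "phosphate_index": 10,
   "strand": "template",
   "promoter": "U1",
   "protein_length": 721,
   "intervals": [
    {
     "lo": 306,
     "hi": 358,
     "grade": "strong",
     "certainty": "exact"
    }
   ],
   "ambiguous": [],
   "excluded": [
    [
     1,
     305
    ],
    [
     359,
     721
    ]
   ],
   "untested": [],
   "conflicts": [],
   "warnings": [],
   "notes": {}
  },
  "12": {
   "phosphate_index": 12,
   "strand": "template",
   "promoter": "U1",
   "protein_length": 721,
   "intervals": [
    {
     "lo": 306,
     "hi": 358,
     "grade": "strong",
     "certainty": "exact"
    }
   ],
   "ambiguous": [],
   "excluded": [
    [
     1,
     305
    ],
    [
     359,
     721
    ]
   ],
   "untested": [],
   "conflicts": [],
   "warnings": [],
   "notes": {}
  },
  "14": {
   "phosphate_index": 14,
   "strand": "template",
   "promoter": "U1",
   "protein_length": 721,
   "intervals": [
    {
     "lo": 1,
     "hi": 721,
     "grade": "unresolved",
     "certainty": "region"
    }
   ],
   "ambiguous": [],
   "excluded": [],
   "untested": [],
   "conflicts": [],
   "warnings": [],
   "notes": {
    "status": "contact position stated; residue interval not restated in this dataset"
   }
  },
  "17": {
   "phosphate_index": 17,
   "strand": "non_template",
   "promoter": "U1",
   "protein_length": 721,
   "intervals": [
    {
     "lo": 1,
     "hi": 721,
     "grade": "unresolved",
     "certainty": "region"
    }
   ],
   "ambiguous": [],
   "excluded": [],
   "untested": [],
   "conflicts": [],
   "warnings": [],
   "notes": {
    "status": "contact position stated; residue interval not restated in this dataset"
   }
  },
  "20": {
   "phosphate_index": 20,
   "strand": "template",
   "promoter": "U1",
   "protein_length": 721,
   "intervals": [
    {
     "lo": 1,
     "hi": 189,
     "grade": "strong",
     "certainty": "region"
    }
   ],
   "ambiguous": [],
   "excluded": [
    [
     190,
     721
    ]
   ],
   "untested": [],
   "conflicts": [],
   "warnings": [],
   "notes": {}
  },
  "22": {
   "phosphate_index": 22,
   "strand": "template",
   "promoter": "U1",
   "protein_length": 721,
   "intervals": [
    {
     "lo": 1,
     "hi": 721,
     "grade": "unresolved",
     "certainty": "region"
    }
   ],
   "ambiguous": [],
   "excluded": [],
   "untested": [],
   "conflicts": [],
   "warnings": [],
   "notes": {
    "status": "contact position stated; residue interval not restated in this dataset"
   }
  },
  "24": {
   "phosphate_index": 24,
   "strand": "template",
   "promoter": "U1",
   "protein_length": 721,
   "intervals": [
    {
     "lo": 1,
     "hi": 721,
     "grade": "unresolved",
     "certainty": "region"
    }
   ],
   "ambiguous": [],
   "excluded": [],
   "untested": [],
   "conflicts": [],
   "warnings": [],
   "notes": {
    "status": "contact position stated; residue interval not restated in this dataset"
   }
  },
  "25": {
   "phosphate_index": 25,
   "strand": "non_template",
   "promoter": "U1",
   "protein_length": 721,
   "intervals": [
    {
     "lo": 1,
     "hi": 721,
     "grade": "unresolved",
     "certainty": "region"
    }
   ],
   "ambiguous": [],
   "excluded": [],
   "untested": [],
   "conflicts": [],
   "warnings": [],
   "notes": {
    "status": "contact position stated; residue interval not restated in this dataset"
   }
  }
 },
 "domains": [
  [
   "N-term",
   1,
   189
  ],
  [
   "Rh",
   190,
   247
  ],
  [
   "Ra",
   248,
   305
  ],
  [
   "Rb",
   306,
   358
  ],
  [
   "Rc",
   359,
   409
  ],
  [
   "Rd",
   410,
   483
  ],
  [
   "C-term",
   484,
   721
  ]
 ]
}
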