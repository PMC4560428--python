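[
  {"node": "CYCD3;1", "value": 1, "periods": [1], "n_attractors": 1,
   "phenotype": "fixed-point arrest in a G2-like configuration"},
  {"node": "SCF", "value": 1, "periods": null,
   "phenotype": "oscillation between G1 and S configurations"},
  {"node": "RBR", "value": 1, "periods": [1], "n_attractors": 1,
   "phenotype": "fixed-point arrest characterizing G1"},
  {"node": "E2Fa", "value": 1, "periods": [10, 8], "n_attractors": 2,
   "basin_percents": [40.48, 59.52],
   "phenotype": "wild-type-like cycle plus an endocycle-like cycle"},
  {"node": "E2Fb", "value": 1, "periods": null,
   "phenotype": "similar to wild type with a shorter S phase"},
  {"node": "E2Fc", "value": 1, "periods": [1], "n_attractors": 1,
   "phenotype": "arrest with only E2Fc and CYCD3;1 present"},
  {"node": "E2Fe", "value": 1, "periods": [1], "n_attractors": 1,
   "phenotype": "arrest in an M-phase configuration"},
  {"node": "MYB77", "value": 1, "periods": [1], "n_attractors": 1,
   "phenotype": "arrest in a mitotic configuration"},
  {"node": "MYB3R1/4", "value": 1, "periods": [1, 1], "n_attractors": 2,
   "phenotype": "two early-G1 arrest points differing in E2Fa"},
  {"node": "CYCB1;1", "value": 1, "periods": [11], "n_attractors": 1,
   "phenotype": "wild-type cycle"},
  {"node": "CDKB1;1", "value": 1, "periods": [11], "n_attractors": 1,
   "phenotype": "wild-type cycle"},
  {"node": "CYCA2;3", "value": 1, "periods": [11], "n_attractors": 1,
   "phenotype": "wild-type cycle"},
  {"node": "KRP1", "value": 1, "periods": [2], "n_attractors": 1,
   "phenotype": "period-2 oscillation between G1 and the G1/S transition"},
  {"node": "APC/C", "value": 1, "periods": [7], "n_attractors": 1,
   "phenotype": "endocycle-like cyclic attractor"},

  {"node": "CYCD3;1", "value": 0, "periods": [2], "n_attractors": 1,
   "phenotype": "period-2 oscillation between G1 and the G1/S transition"},
  {"node": "SCF", "value": 0, "periods": null,
   "phenotype": "near-normal cycle with KRP1 stabilized"},
  {"node": "RBR", "value": 0, "n_attractors": 2,
   "basin_percents": [81.98, 18.02],
   "phenotype": "normal cycle plus a G2-S-G2 oscillation"},
  {"node": "E2Fa", "value": 0, "periods": [1], "n_attractors": 1,
   "phenotype": "Gap-phase arrest with E2Fe and CYCD3;1 present"},
  {"node": "E2Fb", "value": 0, "periods": [1], "n_attractors": 1,
   "phenotype": "arrest at a G1/S-transition configuration"},
  {"node": "E2Fc", "value": 0, "periods": [1], "n_attractors": 1,
   "phenotype": "arrest at an M-phase configuration"},
  {"node": "E2Fe", "value": 0, "periods": [7], "n_attractors": 1,
   "phenotype": "endoreduplication attractor"},
  {"node": "MYB77", "value": 0, "periods": [7], "n_attractors": 1,
   "phenotype": "cycle of seven configurations"},
  {"node": "MYB3R1/4", "value": 0, "periods": [3, 7], "n_attractors": 2,
   "phenotype": "three-configuration endocycle plus a seven-configuration cycle without APC/C"},
  {"node": "CYCB1;1", "value": 0, "periods": [8], "n_attractors": 1,
   "phenotype": "endocycle (APC/C never present)"},
  {"node": "CDKB1;1", "value": 0, "periods": [7], "n_attractors": 1,
   "phenotype": "endoreduplication attractor (the published summary table prints period 11 for this mutant while the published attractor figure shows period 7; the figure value is recorded here)"},
  {"node": "CYCA2;3", "value": 0, "periods": [7], "n_attractors": 1,
   "phenotype": "endocycle"},
  {"node": "KRP1", "value": 0, "periods": [11], "n_attractors": 1,
   "basin_percents": [100.0],
   "phenotype": "unaltered cell cycle"},
  {"node": "APC/C", "value": 0, "periods": [1], "n_attractors": 1,
   "phenotype": "arrest before the completion of mitosis"}
]
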