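{
  "nodes": [
    "CYCD3;1",
    "CYCB1;1",
    "CYCA2;3",
    "CDKB1;1",
    "KRP1",
    "RBR",
    "E2Fa",
    "E2Fb",
    "E2Fc",
    "E2Fe",
    "MYB77",
    "MYB3R1/4",
    "SCF",
    "APC/C"
  ],
  "rule_file_sha256": "df4ae1ce0a47d9c32cd5b1d7068b2ffc814d08f1da25cf1e3043b5b48dee4aa2",
  "phase_scheme": [
    "G1",
    "G1",
    "G1/S",
    "S",
    "S/G2",
    "S/G2",
    "G2",
    "G2/M",
    "M",
    "M",
    "M-exit"
  ],
  "provenance": {
    "CYCD3;1": {
      "inputs": [
        "SCF",
        "KRP1"
      ],
      "signs": [
        -1,
        -1
      ]
    },
    "CYCB1;1": {
      "inputs": [
        "E2Fb",
        "RBR",
        "E2Fc",
        "MYB77",
        "MYB3R1/4",
        "APC/C",
        "KRP1"
      ],
      "signs": [
        1,
        -1,
        -1,
        1,
        1,
        -1,
        -1
      ]
    },
    "CYCA2;3": {
      "inputs": [
        "MYB77",
        "MYB3R1/4",
        "APC/C"
      ],
      "signs": [
        1,
        1,
        -1
      ]
    },
    "CDKB1;1": {
      "inputs": [
        "E2Fb",
        "RBR",
        "E2Fc",
        "MYB77",
        "MYB3R1/4"
      ],
      "signs": [
        1,
        -1,
        -1,
        1,
        1
      ]
    },
    "KRP1": {
      "inputs": [
        "MYB77",
        "MYB3R1/4",
        "SCF",
        "CDKB1;1",
        "CYCA2;3"
      ],
      "signs": [
        1,
        1,
        -1,
        -1,
        -1
      ]
    },
    "RBR": {
      "inputs": [
        "CYCD3;1",
        "KRP1",
        "E2Fa",
        "MYB3R1/4"
      ],
      "signs": [
        -1,
        1,
        1,
        1
      ]
    },
    "E2Fa": {
      "inputs": [
        "E2Fc",
        "CDKB1;1",
        "CYCA2;3",
        "RBR"
      ],
      "signs": [
        -1,
        -1,
        -1,
        -1
      ]
    },
    "E2Fb": {
      "inputs": [
        "E2Fa",
        "RBR"
      ],
      "signs": [
        1,
        -1
      ]
    },
    "E2Fc": {
      "inputs": [
        "E2Fa",
        "RBR",
        "MYB3R1/4",
        "CYCD3;1",
        "KRP1",
        "SCF"
      ],
      "signs": [
        1,
        -1,
        1,
        -1,
        1,
        -1
      ]
    },
    "E2Fe": {
      "inputs": [
        "E2Fb",
        "RBR",
        "E2Fc",
        "MYB77"
      ],
      "signs": [
        1,
        -1,
        -1,
        1
      ]
    },
    "MYB77": {
      "inputs": [
        "E2Fb",
        "RBR"
      ],
      "signs": [
        1,
        -1
      ]
    },
    "MYB3R1/4": {
      "inputs": [
        "MYB77",
        "MYB3R1/4",
        "CYCB1;1",
        "KRP1"
      ],
      "signs": [
        1,
        1,
        1,
        -1
      ]
    },
    "SCF": {
      "inputs": [
        "E2Fb",
        "RBR",
        "MYB3R1/4",
        "APC/C"
      ],
      "signs": [
        1,
        -1,
        1,
        -1
      ]
    },
    "APC/C": {
      "inputs": [
        "E2Fa",
        "RBR",
        "E2Fe",
        "MYB77",
        "MYB3R1/4"
      ],
      "signs": [
        1,
        -1,
        -1,
        1,
        1
      ]
    }
  }
}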