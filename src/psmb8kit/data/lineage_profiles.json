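{
  "positions": [
    13,
    99,
    147,
    150,
    156,
    188,
    189,
    194
  ],
  "A": {
    "13": "I",
    "99": "S",
    "147": "M",
    "150": "E",
    "156": "G",
    "188": "C",
    "189": "K",
    "194": "E"
  },
  "F": {
    "13": "M",
    "99": "T",
    "147": "L",
    "150": "P",
    "156": "A",
    "188": "S",
    "189": "Q",
    "194": "D"
  }
}
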