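[
 {
  "name": "Input",
  "kind": "input",
  "shape": [
   512,
   512,
   3
  ]
 },
 {
  "name": "C1",
  "kind": "C",
  "shape": [
   512,
   512,
   8
  ]
 },
 {
  "name": "BN1",
  "kind": "BN",
  "shape": [
   512,
   512,
   8
  ]
 },
 {
  "name": "A1",
  "kind": "A",
  "shape": [
   512,
   512,
   8
  ]
 },
 {
  "name": "C2",
  "kind": "C",
  "shape": [
   512,
   512,
   8
  ]
 },
 {
  "name": "BN2",
  "kind": "BN",
  "shape": [
   512,
   512,
   8
  ]
 },
 {
  "name": "A2",
  "kind": "A",
  "shape": [
   512,
   512,
   8
  ]
 },
 {
  "name": "C3",
  "kind": "C",
  "shape": [
   512,
   512,
   8
  ]
 },
 {
  "name": "BN3",
  "kind": "BN",
  "shape": [
   512,
   512,
   8
  ]
 },
 {
  "name": "A3",
  "kind": "A",
  "shape": [
   512,
   512,
   8
  ]
 },
 {
  "name": "MP",
  "kind": "MP",
  "shape": [
   256,
   256,
   8
  ]
 },
 {
  "name": "C4",
  "kind": "C",
  "shape": [
   256,
   256,
   16
  ]
 },
 {
  "name": "BN4",
  "kind": "BN",
  "shape": [
   256,
   256,
   16
  ]
 },
 {
  "name": "A4",
  "kind": "A",
  "shape": [
   256,
   256,
   16
  ]
 },
 {
  "name": "C5",
  "kind": "C",
  "shape": [
   256,
   256,
   16
  ]
 },
 {
  "name": "BN5",
  "kind": "BN",
  "shape": [
   256,
   256,
   16
  ]
 },
 {
  "name": "A5",
  "kind": "A",
  "shape": [
   256,
   256,
   16
  ]
 },
 {
  "name": "C6",
  "kind": "C",
  "shape": [
   256,
   256,
   16
  ]
 },
 {
  "name": "BN6",
  "kind": "BN",
  "shape": [
   256,
   256,
   16
  ]
 },
 {
  "name": "A6",
  "kind": "A",
  "shape": [
   256,
   256,
   16
  ]
 },
 {
  "name": "MP",
  "kind": "MP",
  "shape": [
   128,
   128,
   16
  ]
 },
 {
  "name": "C7",
  "kind": "C",
  "shape": [
   128,
   128,
   32
  ]
 },
 {
  "name": "BN7",
  "kind": "BN",
  "shape": [
   128,
   128,
   32
  ]
 },
 {
  "name": "A7",
  "kind": "A",
  "shape": [
   128,
   128,
   32
  ]
 },
 {
  "name": "C8",
  "kind": "C",
  "shape": [
   128,
   128,
   32
  ]
 },
 {
  "name": "BN8",
  "kind": "BN",
  "shape": [
   128,
   128,
   32
  ]
 },
 {
  "name": "A8",
  "kind": "A",
  "shape": [
   128,
   128,
   32
  ]
 },
 {
  "name": "C9",
  "kind": "C",
  "shape": [
   128,
   128,
   32
  ]
 },
 {
  "name": "BN9",
  "kind": "BN",
  "shape": [
   128,
   128,
   32
  ]
 },
 {
  "name": "A9",
  "kind": "A",
  "shape": [
   128,
   128,
   32
  ]
 },
 {
  "name": "MP",
  "kind": "MP",
  "shape": [
   64,
   64,
   32
  ]
 },
 {
  "name": "C10",
  "kind": "C",
  "shape": [
   64,
   64,
   48
  ]
 },
 {
  "name": "BN10",
  "kind": "BN",
  "shape": [
   64,
   64,
   48
  ]
 },
 {
  "name": "A10",
  "kind": "A",
  "shape": [
   64,
   64,
   48
  ]
 },
 {
  "name": "C11",
  "kind": "C",
  "shape": [
   64,
   64,
   48
  ]
 },
 {
  "name": "BN11",
  "kind": "BN",
  "shape": [
   64,
   64,
   48
  ]
 },
 {
  "name": "A11",
  "kind": "A",
  "shape": [
   64,
   64,
   48
  ]
 },
 {
  "name": "C12",
  "kind": "C",
  "shape": [
   64,
   64,
   48
  ]
 },
 {
  "name": "BN12",
  "kind": "BN",
  "shape": [
   64,
   64,
   48
  ]
 },
 {
  "name": "A12",
  "kind": "A",
  "shape": [
   64,
   64,
   48
  ]
 },
 {
  "name": "MP",
  "kind": "MP",
  "shape": [
   32,
   32,
   48
  ]
 },
 {
  "name": "C13",
  "kind": "C",
  "shape": [
   32,
   32,
   64
  ]
 },
 {
  "name": "BN13",
  "kind": "BN",
  "shape": [
   32,
   32,
   64
  ]
 },
 {
  "name": "A13",
  "kind": "A",
  "shape": [
   32,
   32,
   64
  ]
 },
 {
  "name": "C14",
  "kind": "C",
  "shape": [
   32,
   32,
   64
  ]
 },
 {
  "name": "BN14",
  "kind": "BN",
  "shape": [
   32,
   32,
   64
  ]
 },
 {
  "name": "A14",
  "kind": "A",
  "shape": [
   32,
   32,
   64
  ]
 },
 {
  "name": "C15",
  "kind": "C",
  "shape": [
   32,
   32,
   64
  ]
 },
 {
  "name": "BN15",
  "kind": "BN",
  "shape": [
   32,
   32,
   64
  ]
 },
 {
  "name": "A15",
  "kind": "A",
  "shape": [
   32,
   32,
   64
  ]
 },
 {
  "name": "MP",
  "kind": "MP",
  "shape": [
   16,
   16,
   64
  ]
 },
 {
  "name": "C16",
  "kind": "C",
  "shape": [
   16,
   16,
   64
  ]
 },
 {
  "name": "BN16",
  "kind": "BN",
  "shape": [
   16,
   16,
   64
  ]
 },
 {
  "name": "A16",
  "kind": "A",
  "shape": [
   16,
   16,
   64
  ]
 },
 {
  "name": "UPS1",
  "kind": "UPS",
  "shape": [
   32,
   32,
   64
  ]
 },
 {
  "name": "CNC1",
  "kind": "CNC",
  "shape": [
   32,
   32,
   128
  ]
 },
 {
  "name": "C17",
  "kind": "C",
  "shape": [
   32,
   32,
   64
  ]
 },
 {
  "name": "BN17",
  "kind": "BN",
  "shape": [
   32,
   32,
   64
  ]
 },
 {
  "name": "A17",
  "kind": "A",
  "shape": [
   32,
   32,
   64
  ]
 },
 {
  "name": "UPS2",
  "kind": "UPS",
  "shape": [
   64,
   64,
   64
  ]
 },
 {
  "name": "CNC2",
  "kind": "CNC",
  "shape": [
   64,
   64,
   112
  ]
 },
 {
  "name": "C18",
  "kind": "C",
  "shape": [
   64,
   64,
   48
  ]
 },
 {
  "name": "BN18",
  "kind": "BN",
  "shape": [
   64,
   64,
   48
  ]
 },
 {
  "name": "A18",
  "kind": "A",
  "shape": [
   64,
   64,
   48
  ]
 },
 {
  "name": "UPS3",
  "kind": "UPS",
  "shape": [
   128,
   128,
   48
  ]
 },
 {
  "name": "CNC3",
  "kind": "CNC",
  "shape": [
   128,
   128,
   80
  ]
 },
 {
  "name": "C19",
  "kind": "C",
  "shape": [
   128,
   128,
   32
  ]
 },
 {
  "name": "BN19",
  "kind": "BN",
  "shape": [
   128,
   128,
   32
  ]
 },
 {
  "name": "A19",
  "kind": "A",
  "shape": [
   128,
   128,
   32
  ]
 },
 {
  "name": "UPS4",
  "kind": "UPS",
  "shape": [
   256,
   256,
   32
  ]
 },
 {
  "name": "CNC4",
  "kind": "CNC",
  "shape": [
   256,
   256,
   48
  ]
 },
 {
  "name": "C20",
  "kind": "C",
  "shape": [
   256,
   256,
   16
  ]
 },
 {
  "name": "BN20",
  "kind": "BN",
  "shape": [
   256,
   256,
   16
  ]
 },
 {
  "name": "A20",
  "kind": "A",
  "shape": [
   256,
   256,
   16
  ]
 },
 {
  "name": "UPS5",
  "kind": "UPS",
  "shape": [
   512,
   512,
   16
  ]
 },
 {
  "name": "CNC5",
  "kind": "CNC",
  "shape": [
   512,
   512,
   24
  ]
 },
 {
  "name": "C21",
  "kind": "C",
  "shape": [
   512,
   512,
   8
  ]
 },
 {
  "name": "BN21",
  "kind": "BN",
  "shape": [
   512,
   512,
   8
  ]
 },
 {
  "name": "A21",
  "kind": "A",
  "shape": [
   512,
   512,
   8
  ]
 },
 {
  "name": "C22",
  "kind": "C",
  "shape": [
   512,
   512,
   1
  ]
 },
 {
  "name": "A22",
  "kind": "A",
  "shape": [
   512,
   512,
   1
  ]
 }
]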