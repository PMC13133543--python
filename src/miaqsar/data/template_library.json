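{
 "version": 1,
 "units": "angstrom",
 "comment": "Congeneric phenyltriazolinone scaffold: N1-phenyl (para = R1 slot), 1,2,4-triazol-5(4H)-one with N4-methyl, methylene bridge to a five-membered heteroaryl ring with slot atoms X (position 1) and Y (position 5) and substituent slots at ring positions 3 and 5. Bondi radii / Pauling electronegativities are applied downstream.",
 "scaffold": {
  "atoms": [
   [
    "C",
    1.39,
    0.0
   ],
   [
    "C",
    0.695,
    1.2038
   ],
   [
    "C",
    -0.695,
    1.2038
   ],
   [
    "C",
    -1.39,
    0.0
   ],
   [
    "C",
    -0.695,
    -1.2038
   ],
   [
    "C",
    0.695,
    -1.2038
   ],
   [
    "H",
    1.24,
    2.1478
   ],
   [
    "H",
    -1.24,
    2.1478
   ],
   [
    "H",
    -1.24,
    -2.1478
   ],
   [
    "H",
    1.24,
    -2.1478
   ],
   [
    "N",
    2.82,
    0.0
   ],
   [
    "N",
    3.6311,
    1.1164
   ],
   [
    "C",
    4.9436,
    0.69
   ],
   [
    "N",
    4.9436,
    -0.69
   ],
   [
    "C",
    3.6311,
    -1.1164
   ],
   [
    "O",
    3.2541,
    -2.2767
   ],
   [
    "C",
    6.1167,
    -1.5423
   ],
   [
    "H",
    6.9985,
    -2.183
   ],
   [
    "H",
    6.3247,
    -0.4723
   ],
   [
    "H",
    5.1634,
    -2.0707
   ],
   [
    "C",
    6.1571,
    1.5717
   ],
   [
    "H",
    6.7021,
    2.5157
   ],
   [
    "H",
    5.6121,
    2.5157
   ],
   [
    "C",
    7.3706,
    0.69
   ],
   [
    "C",
    8.6831,
    1.1164
   ],
   [
    "C",
    9.4942,
    0.0
   ],
   [
    "H",
    10.5842,
    0.0
   ]
  ],
  "bonds": [
   [
    0,
    1,
    2
   ],
   [
    1,
    2,
    1
   ],
   [
    2,
    3,
    2
   ],
   [
    3,
    4,
    1
   ],
   [
    4,
    5,
    2
   ],
   [
    5,
    0,
    1
   ],
   [
    1,
    6,
    1
   ],
   [
    2,
    7,
    1
   ],
   [
    4,
    8,
    1
   ],
   [
    5,
    9,
    1
   ],
   [
    0,
    10,
    1
   ],
   [
    10,
    11,
    1
   ],
   [
    11,
    12,
    2
   ],
   [
    12,
    13,
    1
   ],
   [
    13,
    14,
    1
   ],
   [
    14,
    10,
    1
   ],
   [
    14,
    15,
    2
   ],
   [
    13,
    16,
    1
   ],
   [
    16,
    17,
    1
   ],
   [
    16,
    18,
    1
   ],
   [
    16,
    19,
    1
   ],
   [
    12,
    20,
    1
   ],
   [
    20,
    21,
    1
   ],
   [
    20,
    22,
    1
   ],
   [
    20,
    23,
    1
   ],
   [
    23,
    24,
    2
   ],
   [
    24,
    25,
    1
   ],
   [
    25,
    26,
    1
   ]
  ]
 },
 "slots": {
  "X": {
   "kind": "ring_atom",
   "position": [
    7.3706,
    -0.69
   ],
   "bond_scaffold": [
    23
   ],
   "bond_slots": [
    "Y"
   ],
   "h_direction": [
    -0.8090169943749473,
    -0.5877852522924732
   ],
   "allowed": [
    "S",
    "O",
    "CH",
    "C"
   ]
  },
  "Y": {
   "kind": "ring_atom",
   "position": [
    8.6831,
    -1.1164
   ],
   "bond_scaffold": [
    25
   ],
   "bond_slots": [],
   "h_direction": [
    0.30901699437494745,
    -0.9510565162951535
   ],
   "allowed": [
    "CH",
    "S",
    "C"
   ]
  },
  "R1": {
   "kind": "substituent",
   "attach_scaffold": 3,
   "direction": [
    -1.0,
    0.0
   ],
   "allowed": [
    "H",
    "Cl",
    "CH3",
    "CF3",
    "Br",
    "F"
   ]
  },
  "R2_3": {
   "kind": "substituent",
   "attach_scaffold": 24,
   "direction": [
    0.30901699437494745,
    0.9510565162951535
   ],
   "allowed": [
    "H",
    "CH3",
    "Br"
   ]
  },
  "R2_5": {
   "kind": "substituent",
   "attach_slot": "Y",
   "direction": [
    0.30901699437494745,
    -0.9510565162951535
   ],
   "allowed": [
    "H",
    "CH3"
   ]
  }
 },
 "substituents": {
  "H": {
   "atoms": [
    [
     "H",
     1.09,
     0.0
    ]
   ],
   "bonds": [
    [
     -1,
     0,
     1
    ]
   ]
  },
  "F": {
   "atoms": [
    [
     "F",
     1.35,
     0.0
    ]
   ],
   "bonds": [
    [
     -1,
     0,
     1
    ]
   ]
  },
  "Cl": {
   "atoms": [
    [
     "Cl",
     1.74,
     0.0
    ]
   ],
   "bonds": [
    [
     -1,
     0,
     1
    ]
   ]
  },
  "Br": {
   "atoms": [
    [
     "Br",
     1.9,
     0.0
    ]
   ],
   "bonds": [
    [
     -1,
     0,
     1
    ]
   ]
  },
  "CH3": {
   "atoms": [
    [
     "C",
     1.5,
     0.0
    ],
    [
     "H",
     2.59,
     0.0
    ],
    [
     "H",
     1.0393,
     0.9879
    ],
    [
     "H",
     1.0393,
     -0.9879
    ]
   ],
   "bonds": [
    [
     -1,
     0,
     1
    ],
    [
     0,
     1,
     1
    ],
    [
     0,
     2,
     1
    ],
    [
     0,
     3,
     1
    ]
   ]
  },
  "CF3": {
   "atoms": [
    [
     "C",
     1.5,
     0.0
    ],
    [
     "F",
     2.85,
     0.0
    ],
    [
     "F",
     0.9295,
     1.2235
    ],
    [
     "F",
     0.9295,
     -1.2235
    ]
   ],
   "bonds": [
    [
     -1,
     0,
     1
    ],
    [
     0,
     1,
     1
    ],
    [
     0,
     2,
     1
    ],
    [
     0,
     3,
     1
    ]
   ]
  }
 }
}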