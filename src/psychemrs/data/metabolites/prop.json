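{
 "concentration_mm": 10.0,
 "name": "Prop",
 "reference_peaks": [
  [
   "CH3",
   0.98
  ],
  [
   "CH2",
   2.3
  ]
 ],
 "source_note": "Propionate. CH3 0.98 ppm and CH2 2.30 ppm pinned to the printed two-compartment phantom positions (the most upfield multiplet is assigned to CH3); 3J(CH3,CH2) = 7.6 Hz from standard propionate literature values. Intra-group J irrelevant for equivalent spins, set 0.",
 "subsystems": [
  {
   "j_hz": [
    [
     0.0,
     0.0,
     0.0,
     7.6,
     7.6
    ],
    [
     0.0,
     0.0,
     0.0,
     7.6,
     7.6
    ],
    [
     0.0,
     0.0,
     0.0,
     7.6,
     7.6
    ],
    [
     7.6,
     7.6,
     7.6,
     0.0,
     0.0
    ],
    [
     7.6,
     7.6,
     7.6,
     0.0,
     0.0
    ]
   ],
   "labels": [
    "CH3a",
    "CH3b",
    "CH3c",
    "CH2a",
    "CH2b"
   ],
   "shifts_ppm": [
    0.98,
    0.98,
    0.98,
    2.3,
    2.3
   ]
  }
 ]
}
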