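{
 "concentration_mm": 10.0,
 "name": "GABA",
 "reference_peaks": [
  [
   "2-CH2",
   2.28
  ],
  [
   "3-CH2",
   1.89
  ],
  [
   "4-CH2",
   2.97
  ]
 ],
 "source_note": "gamma-aminobutyric acid. N-CH2 pinned at 2.97 ppm (printed position); 2-CH2 2.28 ppm and 3-CH2 1.89 ppm and 3J = 7.3 Hz from standard literature values.",
 "subsystems": [
  {
   "j_hz": [
    [
     0.0,
     0.0,
     7.3,
     7.3,
     0.0,
     0.0
    ],
    [
     0.0,
     0.0,
     7.3,
     7.3,
     0.0,
     0.0
    ],
    [
     7.3,
     7.3,
     0.0,
     0.0,
     7.3,
     7.3
    ],
    [
     7.3,
     7.3,
     0.0,
     0.0,
     7.3,
     7.3
    ],
    [
     0.0,
     0.0,
     7.3,
     7.3,
     0.0,
     0.0
    ],
    [
     0.0,
     0.0,
     7.3,
     7.3,
     0.0,
     0.0
    ]
   ],
   "labels": [
    "H2a",
    "H2b",
    "H3a",
    "H3b",
    "H4a",
    "H4b"
   ],
   "shifts_ppm": [
    2.28,
    2.28,
    1.89,
    1.89,
    2.97,
    2.97
   ]
  }
 ]
}
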