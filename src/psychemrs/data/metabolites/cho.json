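{
 "concentration_mm": 10.0,
 "name": "Cho",
 "reference_peaks": [
  [
   "N(CH3)3",
   3.16
  ],
  [
   "N-CH2",
   3.51
  ],
  [
   "O-CH2",
   4.05
  ]
 ],
 "source_note": "Choline chloride. N(CH3)3 singlet pinned at 3.16 ppm (printed position); N-CH2 3.51, O-CH2 4.05 ppm with an effective 3J = 5.0 Hz (A2B2 approximation of the AA'BB' system) from literature.",
 "subsystems": [
  {
   "j_hz": [
    [
     0.0
    ]
   ],
   "labels": [
    "NMe3"
   ],
   "shifts_ppm": [
    3.16
   ],
   "weight": 9
  },
  {
   "j_hz": [
    [
     0.0,
     0.0,
     5.0,
     5.0
    ],
    [
     0.0,
     0.0,
     5.0,
     5.0
    ],
    [
     5.0,
     5.0,
     0.0,
     0.0
    ],
    [
     5.0,
     5.0,
     0.0,
     0.0
    ]
   ],
   "labels": [
    "OCH2a",
    "OCH2b",
    "NCH2a",
    "NCH2b"
   ],
   "shifts_ppm": [
    4.05,
    4.05,
    3.51,
    3.51
   ]
  }
 ]
}
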