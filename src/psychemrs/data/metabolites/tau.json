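{
 "concentration_mm": 10.0,
 "name": "Tau",
 "reference_peaks": [
  [
   "N-CH2",
   3.22
  ],
  [
   "S-CH2",
   3.42
  ]
 ],
 "source_note": "Taurine. N-CH2 pinned at 3.22 ppm (printed overlap region); S-CH2 3.42 ppm and 3J = 6.7 Hz from literature (A2B2 approximation).",
 "subsystems": [
  {
   "j_hz": [
    [
     0.0,
     0.0,
     6.7,
     6.7
    ],
    [
     0.0,
     0.0,
     6.7,
     6.7
    ],
    [
     6.7,
     6.7,
     0.0,
     0.0
    ],
    [
     6.7,
     6.7,
     0.0,
     0.0
    ]
   ],
   "labels": [
    "NCH2a",
    "NCH2b",
    "SCH2a",
    "SCH2b"
   ],
   "shifts_ppm": [
    3.22,
    3.22,
    3.42,
    3.42
   ]
  }
 ]
}
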