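{
 "concentration_mm": 10.0,
 "name": "NAA",
 "reference_peaks": [
  [
   "acetyl-CH3",
   1.98
  ],
  [
   "CH2",
   2.58
  ]
 ],
 "source_note": "N-acetyl aspartate. Acetyl CH3 singlet pinned at 1.98 ppm (printed position); aspartyl CH 4.38, CH2 2.67/2.49 ppm, J = 3.9/9.8 Hz, geminal -15.6 Hz from literature.",
 "subsystems": [
  {
   "j_hz": [
    [
     0.0
    ]
   ],
   "labels": [
    "Ac-CH3"
   ],
   "shifts_ppm": [
    1.98
   ],
   "weight": 3
  },
  {
   "j_hz": [
    [
     0.0,
     3.9,
     9.8
    ],
    [
     3.9,
     0.0,
     -15.6
    ],
    [
     9.8,
     -15.6,
     0.0
    ]
   ],
   "labels": [
    "CH",
    "CH2a",
    "CH2b"
   ],
   "shifts_ppm": [
    4.38,
    2.67,
    2.49
   ]
  }
 ]
}
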