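{
 "concentration_mm": 10.0,
 "name": "Asp",
 "reference_peaks": [
  [
   "CH",
   3.86
  ],
  [
   "CH2",
   2.75
  ]
 ],
 "source_note": "Aspartate. CH pinned at 3.86 ppm (printed position); CH2 2.80/2.70 ppm, J = 3.6/9.1 Hz, geminal -17.4 Hz from literature.",
 "subsystems": [
  {
   "j_hz": [
    [
     0.0,
     3.6,
     9.1
    ],
    [
     3.6,
     0.0,
     -17.4
    ],
    [
     9.1,
     -17.4,
     0.0
    ]
   ],
   "labels": [
    "CH",
    "CH2a",
    "CH2b"
   ],
   "shifts_ppm": [
    3.86,
    2.8,
    2.7
   ]
  }
 ]
}
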