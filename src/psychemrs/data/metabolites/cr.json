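{
 "concentration_mm": 10.0,
 "name": "Cr",
 "reference_peaks": [
  [
   "N-CH3",
   3.0
  ],
  [
   "CH2",
   3.93
  ]
 ],
 "source_note": "Creatine. N-CH3 singlet pinned at 3.00 ppm (printed position); CH2 singlet 3.93 ppm from literature.",
 "subsystems": [
  {
   "j_hz": [
    [
     0.0
    ]
   ],
   "labels": [
    "N-CH3"
   ],
   "shifts_ppm": [
    3.0
   ],
   "weight": 3
  },
  {
   "j_hz": [
    [
     0.0
    ]
   ],
   "labels": [
    "CH2"
   ],
   "shifts_ppm": [
    3.93
   ],
   "weight": 2
  }
 ]
}
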