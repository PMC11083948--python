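{
 "concentration_mm": 55000.0,
 "name": "water",
 "reference_peaks": [
  [
   "H2O",
   4.7
  ]
 ],
 "source_note": "Stress-test fixture only: a giant on-carrier singlet at 4.70 ppm. Water suppression is not simulated; not part of any bundled phantom.",
 "subsystems": [
  {
   "j_hz": [
    [
     0.0
    ]
   ],
   "labels": [
    "H2O"
   ],
   "shifts_ppm": [
    4.7
   ],
   "t2_s": 0.05,
   "weight": 2
  }
 ]
}
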