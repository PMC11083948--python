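{
 "concentration_mm": 10.0,
 "name": "mI",
 "reference_peaks": [
  [
   "H5",
   3.26
  ],
  [
   "H1/H3",
   3.52
  ],
  [
   "H4/H6",
   3.61
  ],
  [
   "H2",
   4.09
  ]
 ],
 "source_note": "myo-inositol. H2 pinned at 4.09 ppm and H5 at 3.26 ppm (printed regions); H1/H3 3.52 ppm, H4/H6 3.61 ppm and ring couplings J12=J23=2.9, J34=J61=9.9, J45=J56=9.5 Hz from literature. Strongly coupled: singlet positions carry second-order shifts of order J^2/(2*dnu).",
 "subsystems": [
  {
   "j_hz": [
    [
     0.0,
     2.9,
     0.0,
     0.0,
     0.0,
     9.9
    ],
    [
     2.9,
     0.0,
     2.9,
     0.0,
     0.0,
     0.0
    ],
    [
     0.0,
     2.9,
     0.0,
     9.9,
     0.0,
     0.0
    ],
    [
     0.0,
     0.0,
     9.9,
     0.0,
     9.5,
     0.0
    ],
    [
     0.0,
     0.0,
     0.0,
     9.5,
     0.0,
     9.5
    ],
    [
     9.9,
     0.0,
     0.0,
     0.0,
     9.5,
     0.0
    ]
   ],
   "labels": [
    "H1",
    "H2",
    "H3",
    "H4",
    "H5",
    "H6"
   ],
   "shifts_ppm": [
    3.52,
    4.09,
    3.52,
    3.61,
    3.26,
    3.61
   ]
  }
 ]
}
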