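{
 "version": "1.0.0",
 "units": "mm",
 "segments": {
  "pelvis": {
   "length_mm": 180.0,
   "parent": null,
   "origin_height_mm": 930.0
  },
  "femur_r": {
   "length_mm": 400.0,
   "parent": "pelvis",
   "offset_in_parent": [
    0.0,
    -70.0,
    90.0
   ]
  },
  "tibia_r": {
   "length_mm": 380.0,
   "parent": "femur_r",
   "offset_in_parent": [
    0.0,
    -400.0,
    0.0
   ]
  },
  "foot_r": {
   "length_mm": 150.0,
   "parent": "tibia_r",
   "offset_in_parent": [
    0.0,
    -380.0,
    0.0
   ]
  },
  "femur_l": {
   "length_mm": 400.0,
   "parent": "pelvis",
   "offset_in_parent": [
    0.0,
    -70.0,
    -90.0
   ]
  },
  "tibia_l": {
   "length_mm": 380.0,
   "parent": "femur_l",
   "offset_in_parent": [
    0.0,
    -400.0,
    0.0
   ]
  },
  "foot_l": {
   "length_mm": 150.0,
   "parent": "tibia_l",
   "offset_in_parent": [
    0.0,
    -380.0,
    0.0
   ]
  }
 },
 "landmarks": {
  "RASI": {
   "segment": "pelvis",
   "position": [
    10.0,
    0.0,
    120.0
   ]
  },
  "LASI": {
   "segment": "pelvis",
   "position": [
    10.0,
    0.0,
    -120.0
   ]
  },
  "PSY": {
   "segment": "pelvis",
   "position": [
    30.0,
    -80.0,
    0.0
   ]
  },
  "RHJC": {
   "segment": "femur_r",
   "position": [
    0.0,
    0.0,
    0.0
   ]
  },
  "RKJC": {
   "segment": "femur_r",
   "position": [
    0.0,
    -400.0,
    0.0
   ]
  },
  "RTIB": {
   "segment": "tibia_r",
   "position": [
    0.0,
    0.0,
    0.0
   ]
  },
  "RAJC": {
   "segment": "tibia_r",
   "position": [
    0.0,
    -380.0,
    0.0
   ]
  },
  "RHEE": {
   "segment": "foot_r",
   "position": [
    -60.0,
    -70.0,
    0.0
   ]
  },
  "RTOE": {
   "segment": "foot_r",
   "position": [
    150.0,
    -60.0,
    0.0
   ]
  },
  "LHJC": {
   "segment": "femur_l",
   "position": [
    0.0,
    0.0,
    0.0
   ]
  },
  "LKJC": {
   "segment": "femur_l",
   "position": [
    0.0,
    -400.0,
    0.0
   ]
  },
  "LTIB": {
   "segment": "tibia_l",
   "position": [
    0.0,
    0.0,
    0.0
   ]
  },
  "LAJC": {
   "segment": "tibia_l",
   "position": [
    0.0,
    -380.0,
    0.0
   ]
  },
  "LHEE": {
   "segment": "foot_l",
   "position": [
    -60.0,
    -70.0,
    0.0
   ]
  },
  "LTOE": {
   "segment": "foot_l",
   "position": [
    150.0,
    -60.0,
    0.0
   ]
  }
 },
 "stretch_prone": [
  "TFL",
  "Iliacus",
  "Vas_Int"
 ],
 "gait_fourier": {
  "hip_deg": {
   "mean": 5.0,
   "cos": [
    20.0,
    -3.0,
    1.0
   ],
   "sin": [
    8.0,
    2.0,
    0.0
   ]
  },
  "knee_deg": {
   "mean": 22.0,
   "cos": [
    -5.0,
    -15.0,
    2.0
   ],
   "sin": [
    -18.0,
    6.0,
    0.0
   ]
  },
  "ankle_deg": {
   "mean": 0.0,
   "cos": [
    -3.0,
    -4.0,
    1.0
   ],
   "sin": [
    5.0,
    3.0,
    0.0
   ]
  }
 },
 "muscles": [
  {
   "name": "Glut_Max1",
   "origin_segment": "pelvis",
   "origin": [
    -120.0,
    40.0,
    60.0
   ],
   "insertion_segment": "femur_r",
   "insertion": [
    -25.0,
    -90.0,
    15.0
   ],
   "pennation_deg": 5.0,
   "fiber_length_cm": 14.2,
   "L0_generic_mm": 201.8
  },
  {
   "name": "TFL",
   "origin_segment": "pelvis",
   "origin": [
    10.0,
    5.0,
    115.0
   ],
   "insertion_segment": "tibia_r",
   "insertion": [
    20.0,
    -60.0,
    40.0
   ],
   "pennation_deg": 3.0,
   "fiber_length_cm": 9.5,
   "L0_generic_mm": 512.2
  },
  {
   "name": "Iliacus",
   "origin_segment": "pelvis",
   "origin": [
    -30.0,
    10.0,
    30.0
   ],
   "insertion_segment": "femur_r",
   "insertion": [
    5.0,
    -80.0,
    -10.0
   ],
   "pennation_deg": 7.0,
   "fiber_length_cm": 10.0,
   "L0_generic_mm": 161.6
  },
  {
   "name": "Pectineus",
   "origin_segment": "pelvis",
   "origin": [
    20.0,
    -60.0,
    20.0
   ],
   "insertion_segment": "femur_r",
   "insertion": [
    -10.0,
    -120.0,
    -5.0
   ],
   "pennation_deg": 0.0,
   "fiber_length_cm": 13.3,
   "L0_generic_mm": 137.1
  },
  {
   "name": "Vas_Int",
   "origin_segment": "femur_r",
   "origin": [
    15.0,
    -120.0,
    5.0
   ],
   "insertion_segment": "tibia_r",
   "insertion": [
    40.0,
    -40.0,
    0.0
   ],
   "pennation_deg": 3.0,
   "fiber_length_cm": 8.7,
   "L0_generic_mm": 330.9
  },
  {
   "name": "Med_Gas",
   "origin_segment": "femur_r",
   "origin": [
    -15.0,
    -380.0,
    -20.0
   ],
   "insertion_segment": "foot_r",
   "insertion": [
    -60.0,
    -65.0,
    -5.0
   ],
   "pennation_deg": 17.0,
   "fiber_length_cm": 6.0,
   "L0_generic_mm": 459.3
  },
  {
   "name": "Tib_Ant",
   "origin_segment": "tibia_r",
   "origin": [
    25.0,
    -100.0,
    10.0
   ],
   "insertion_segment": "foot_r",
   "insertion": [
    90.0,
    -40.0,
    -20.0
   ],
   "pennation_deg": 5.0,
   "fiber_length_cm": 9.8,
   "L0_generic_mm": 327.8
  },
  {
   "name": "Tib_Post",
   "origin_segment": "tibia_r",
   "origin": [
    -15.0,
    -80.0,
    5.0
   ],
   "insertion_segment": "foot_r",
   "insertion": [
    40.0,
    -50.0,
    -25.0
   ],
   "pennation_deg": 12.0,
   "fiber_length_cm": 3.1,
   "L0_generic_mm": 355.4
  },
  {
   "name": "Soleus",
   "origin_segment": "tibia_r",
   "origin": [
    -20.0,
    -60.0,
    5.0
   ],
   "insertion_segment": "foot_r",
   "insertion": [
    -60.0,
    -65.0,
    -5.0
   ],
   "pennation_deg": 25.0,
   "fiber_length_cm": 3.0,
   "L0_generic_mm": 387.0
  }
 ]
}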