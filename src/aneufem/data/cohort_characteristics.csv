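case_id,diagnostic_diameter_mm,max_von_mises_mpa,max_equivalent_strain_percent,max_displacement_mm
T1-P2,48,0.35,50,13
T1-P5,51,0.37,50,9
T1-P6,58,0.6,80,24
T1-P9,68,0.35,50,18
T1-P10,48,0.55,70,35
T1-P11,50,0.25,40,12
T1-P14,50,0.45,60,21
T1-P16,55,0.4,50,9
T2-P2,49,0.7,70,14
T2-P3,61,0.3,35,11
T2-P13,51,0.3,35,14
T2-P14,50,0.4,50,18
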