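case_id,systolic_diameter_mm,ppsm_kpa,risk_percent
T1-P2,66,101.54,82.20
T1-P5,63,140.00,90.74
T1-P6,82,68.33,68.70
T1-P9,86,95.56,80.30
T1-P10,83,47.43,55.35
T1-P11,55,91.67,78.95
T1-P14,71,67.62,68.32
T1-P16,64,142.22,91.09
T2-P2,98,140.00,90.74
T2-P3,72,130.91,89.20
T2-P13,65,92.86,79.37
T2-P14,68,75.56,72.32
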