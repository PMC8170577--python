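outcome,group,bmi_low,bmi_high,hr,ci_low,ci_high
uami,18.5-24.9,18.5,25.0,1.0,,
uami,25.0-29.9,25.0,30.0,1.03,1.02,1.04
uami,30.0-34.9,30.0,35.0,1.11,1.09,1.12
uami,35.0-39.9,35.0,40.0,1.14,1.12,1.17
uami,40.0-44.9,40.0,45.0,1.18,1.14,1.23
stroke_tia,18.5-24.9,18.5,25.0,1.0,,
stroke_tia,25.0-29.9,25.0,30.0,0.92,0.91,0.94
stroke_tia,30.0-34.9,30.0,35.0,0.94,0.92,0.95
stroke_tia,35.0-39.9,35.0,40.0,0.98,0.95,1.00
stroke_tia,40.0-44.9,40.0,45.0,1.02,0.98,1.06
t2d,18.5-24.9,18.5,25.0,1.0,,
t2d,25.0-29.9,25.0,30.0,2.30,2.27,2.34
t2d,30.0-34.9,30.0,35.0,4.73,4.65,4.80
t2d,35.0-39.9,35.0,40.0,7.81,7.67,7.96
t2d,40.0-44.9,40.0,45.0,10.8,10.5,11.0
mortality,18.5-24.9,18.5,25.0,1.0,,
mortality,25.0-29.9,25.0,30.0,0.77,0.76,0.77
mortality,30.0-34.9,30.0,35.0,0.81,0.80,0.82
mortality,35.0-39.9,35.0,40.0,0.95,0.94,0.97
mortality,40.0-44.9,40.0,45.0,1.21,1.18,1.24
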