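outcome,series,group,rate
cv_total,observed,18.5-24.9,7.8
cv_total,observed,25.0-29.9,7.6
cv_total,observed,30.0-34.9,7.9
cv_total,observed,35.0-39.9,8.2
cv_total,observed,40.0-44.9,8.5
cv_total,com8_base,18.5-24.9,8.0
cv_total,com8_base,25.0-29.9,8.3
cv_total,com8_base,30.0-34.9,8.7
cv_total,com8_base,35.0-39.9,9.2
cv_total,com8_base,40.0-44.9,9.4
cv_total,com8_scenario,18.5-24.9,8.3
cv_total,com8_scenario,25.0-29.9,8.6
cv_total,com8_scenario,30.0-34.9,9.1
cv_total,com8_scenario,35.0-39.9,9.7
cv_total,com8_scenario,40.0-44.9,9.9
cv_total,com61_base,18.5-24.9,6.0
cv_total,com61_base,25.0-29.9,6.2
cv_total,com61_base,30.0-34.9,6.6
cv_total,com61_base,35.0-39.9,7.0
cv_total,com61_base,40.0-44.9,7.1
uami,observed,18.5-24.9,3.4
uami,observed,25.0-29.9,3.5
uami,observed,30.0-34.9,3.8
uami,observed,35.0-39.9,3.9
uami,observed,40.0-44.9,4.0
uami,com8_base,18.5-24.9,6.0
uami,com8_base,25.0-29.9,6.3
uami,com8_base,30.0-34.9,6.6
uami,com8_base,35.0-39.9,6.9
uami,com8_base,40.0-44.9,7.1
uami,com8_scenario,18.5-24.9,6.2
uami,com8_scenario,25.0-29.9,6.5
uami,com8_scenario,30.0-34.9,6.9
uami,com8_scenario,35.0-39.9,7.3
uami,com8_scenario,40.0-44.9,7.5
uami,com61_base,18.5-24.9,4.5
uami,com61_base,25.0-29.9,4.7
uami,com61_base,30.0-34.9,4.9
uami,com61_base,35.0-39.9,5.2
uami,com61_base,40.0-44.9,5.3
stroke_tia,observed,18.5-24.9,4.4
stroke_tia,observed,25.0-29.9,4.1
stroke_tia,observed,30.0-34.9,4.1
stroke_tia,observed,35.0-39.9,4.3
stroke_tia,observed,40.0-44.9,4.5
stroke_tia,com8_base,18.5-24.9,2.0
stroke_tia,com8_base,25.0-29.9,2.1
stroke_tia,com8_base,30.0-34.9,2.2
stroke_tia,com8_base,35.0-39.9,2.3
stroke_tia,com8_base,40.0-44.9,2.3
stroke_tia,com8_scenario,18.5-24.9,2.0
stroke_tia,com8_scenario,25.0-29.9,2.1
stroke_tia,com8_scenario,30.0-34.9,2.3
stroke_tia,com8_scenario,35.0-39.9,2.4
stroke_tia,com8_scenario,40.0-44.9,2.5
stroke_tia,com61_base,18.5-24.9,1.5
stroke_tia,com61_base,25.0-29.9,1.6
stroke_tia,com61_base,30.0-34.9,1.7
stroke_tia,com61_base,35.0-39.9,1.8
stroke_tia,com61_base,40.0-44.9,1.8
t2d,observed,18.5-24.9,2.1
t2d,observed,25.0-29.9,4.8
t2d,observed,30.0-34.9,9.9
t2d,observed,35.0-39.9,16.4
t2d,observed,40.0-44.9,22.7
t2d,com8_base,18.5-24.9,1.0
t2d,com8_base,25.0-29.9,2.2
t2d,com8_base,30.0-34.9,4.2
t2d,com8_base,35.0-39.9,6.6
t2d,com8_base,40.0-44.9,7.6
t2d,com8_scenario,18.5-24.9,2.7
t2d,com8_scenario,25.0-29.9,4.8
t2d,com8_scenario,30.0-34.9,8.0
t2d,com8_scenario,35.0-39.9,11.6
t2d,com8_scenario,40.0-44.9,13.1
t2d,com61_base,18.5-24.9,1.1
t2d,com61_base,25.0-29.9,2.3
t2d,com61_base,30.0-34.9,4.2
t2d,com61_base,35.0-39.9,6.5
t2d,com61_base,40.0-44.9,7.5
mortality,observed,18.5-24.9,11.6
mortality,observed,25.0-29.9,8.9
mortality,observed,30.0-34.9,9.4
mortality,observed,35.0-39.9,11.0
mortality,observed,40.0-44.9,14.0
mortality,com8_base,18.5-24.9,4.8
mortality,com8_base,25.0-29.9,4.9
mortality,com8_base,30.0-34.9,5.0
mortality,com8_base,35.0-39.9,5.1
mortality,com8_base,40.0-44.9,5.2
mortality,com8_scenario,18.5-24.9,4.9
mortality,com8_scenario,25.0-29.9,5.0
mortality,com8_scenario,30.0-34.9,5.1
mortality,com8_scenario,35.0-39.9,5.3
mortality,com8_scenario,40.0-44.9,5.3
mortality,com61_base,18.5-24.9,3.8
mortality,com61_base,25.0-29.9,3.8
mortality,com61_base,30.0-34.9,3.9
mortality,com61_base,35.0-39.9,4.0
mortality,com61_base,40.0-44.9,4.0
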