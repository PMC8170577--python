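group,n,age_years,bmi,height_m,smoking_pct,women_pct,antihypertensive_pct,lipid_lowering_pct,sbp_mmhg,total_chol_mgdl,hdl_mgdl,hba1c_pct,triglycerides_mgdl,tg_ge_150_pct,no_dysglycemia_pct,prediabetes_pct,t2d_pct,t2d_duration_years
18.5-24.9,1099106,48.5,22.5,1.68,49.3,64.6,14.7,8.3,128.2,203.7,61.0,7.5,118.9,22.4,95.3,2.0,2.7,5.9
25.0-29.9,1074953,53.1,27.3,1.69,50.2,49.7,22.3,13.9,135.4,207.8,53.9,7.6,152.2,40.0,90.2,4.1,5.7,5.0
30.0-34.9,507425,52.1,32.1,1.68,50.6,53.1,26.1,15.7,138.3,208.0,50.4,7.7,175.0,51.7,85.5,5.9,8.6,4.5
35.0-39.9,176237,49.3,37.0,1.66,48.8,62.9,26.7,14.6,139.4,206.2,48.8,7.8,180.1,54.3,82.5,6.9,10.6,4.3
40.0-44.9,67231,47.4,42.3,1.65,47.3,70.9,28.5,14.9,140.0,201.2,47.5,7.8,177.0,53.8,78.8,6.7,14.5,4.1
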