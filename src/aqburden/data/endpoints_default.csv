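name,category,duration,beta,baseline_incidence,cost_rule,unit_cost,vsl_weight,in_affected_total
all_cause_mortality,mortality,chronic,0.00070,0.0060,mortality_bound,0,0,true
cardiovascular_mortality,mortality,chronic,0.00053,0.0021,mortality_bound,0,0,false
respiratory_mortality,mortality,chronic,0.00143,0.0009,mortality_bound,0,0,false
lung_cancer_mortality,mortality,chronic,0.00126,0.0006,mortality_bound,0,0,false
cardiovascular_hospitalization,morbidity,acute,0.00068,0.0200,per_case_fixed,1230,0,true
chronic_bronchitis,morbidity,chronic,0.00448,0.0040,vsl_fraction,0,0.055,true
acute_bronchitis,morbidity,acute,0.00550,0.0200,per_case_fixed,32,0,true
asthma_attack,morbidity,acute,0.00210,0.4000,per_case_fixed,34.2,0,true
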