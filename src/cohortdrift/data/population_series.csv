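label,time,prevalence,source
non_english_cob,1996,0.160,census
non_english_cob,2001/2,0.170,census
non_english_cob,2005/6,0.166,census
non_english_cob,1996,0.121,cohort
non_english_cob,2001/2,0.101,cohort
non_english_cob,2005/6,0.094,cohort
current_or_ex_smoker,1995/6,0.353,health-survey
current_or_ex_smoker,2005,0.296,health-survey
current_or_ex_smoker,1995/6,0.379,cohort
current_or_ex_smoker,2005,0.354,cohort
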