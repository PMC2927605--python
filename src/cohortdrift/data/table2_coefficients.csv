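factor,category,outcome,odds_ratio,ci_low,ci_high
country_of_birth,Other English speaking,dead,0.98,0.84,1.15
country_of_birth,Other English speaking,frail,0.97,0.70,1.33
country_of_birth,Other English speaking,withdrawn,0.95,0.76,1.19
country_of_birth,Other English speaking,lost,1.18,0.95,1.47
country_of_birth,Other,dead,0.95,0.78,1.16
country_of_birth,Other,frail,1.17,0.83,1.67
country_of_birth,Other,withdrawn,1.93,1.55,2.42
country_of_birth,Other,lost,2.03,1.62,2.54
highest_qualification,Certificate/Diploma,dead,1.24,0.89,1.72
highest_qualification,Certificate/Diploma,frail,1.05,0.55,2.00
highest_qualification,Certificate/Diploma,withdrawn,1.54,0.89,2.68
highest_qualification,Certificate/Diploma,lost,0.81,0.52,1.27
highest_qualification,Trade/Apprenticeship,dead,1.12,0.75,1.66
highest_qualification,Trade/Apprenticeship,frail,1.49,0.73,3.04
highest_qualification,Trade/Apprenticeship,withdrawn,2.27,1.25,4.13
highest_qualification,Trade/Apprenticeship,lost,1.10,0.66,1.83
highest_qualification,Any high school,dead,1.31,0.99,1.74
highest_qualification,Any high school,frail,1.19,0.69,2.05
highest_qualification,Any high school,withdrawn,2.28,1.41,3.70
highest_qualification,Any high school,lost,1.17,0.81,1.68
highest_qualification,No formal qualification,dead,1.51,1.13,2.01
highest_qualification,No formal qualification,frail,1.41,0.81,2.47
highest_qualification,No formal qualification,withdrawn,3.54,2.18,5.76
highest_qualification,No formal qualification,lost,1.20,0.83,1.75
bmi_group,Overweight,dead,0.86,0.76,0.97
bmi_group,Overweight,frail,0.91,0.72,1.14
bmi_group,Overweight,withdrawn,1.07,0.92,1.25
bmi_group,Overweight,lost,1.11,0.94,1.31
bmi_group,Obese,dead,0.91,0.77,1.07
bmi_group,Obese,frail,0.79,0.57,1.10
bmi_group,Obese,withdrawn,0.62,0.48,0.79
bmi_group,Obese,lost,1.09,0.87,1.37
bmi_group,Underweight,dead,2.17,1.62,2.92
bmi_group,Underweight,frail,1.72,1.00,2.97
bmi_group,Underweight,withdrawn,1.04,0.64,1.70
bmi_group,Underweight,lost,0.77,0.43,1.36
physical_activity,None or very low,dead,1.75,1.55,1.97
physical_activity,None or very low,frail,1.08,0.85,1.38
physical_activity,None or very low,withdrawn,1.34,1.14,1.59
physical_activity,None or very low,lost,1.19,1.00,1.42
alcohol,Non-drinker,dead,1.38,1.20,1.58
alcohol,Non-drinker,frail,1.34,1.02,1.75
alcohol,Non-drinker,withdrawn,1.15,0.96,1.38
alcohol,Non-drinker,lost,1.13,0.93,1.37
alcohol,Rarely drinks,dead,1.21,1.06,1.39
alcohol,Rarely drinks,frail,1.43,1.09,1.86
alcohol,Rarely drinks,withdrawn,0.92,0.76,1.10
alcohol,Rarely drinks,lost,1.13,0.94,1.37
alcohol,Risky or high-risk drinker,dead,1.02,0.76,1.37
alcohol,Risky or high-risk drinker,frail,1.31,0.74,2.32
alcohol,Risky or high-risk drinker,withdrawn,0.84,0.54,1.31
alcohol,Risky or high-risk drinker,lost,0.74,0.46,1.18
smoking,Ex-smoker,dead,1.45,1.29,1.64
smoking,Ex-smoker,frail,1.10,0.87,1.39
smoking,Ex-smoker,withdrawn,1.00,0.85,1.19
smoking,Ex-smoker,lost,1.25,1.06,1.48
smoking,Smoker,dead,2.73,2.22,3.36
smoking,Smoker,frail,1.26,0.80,1.97
smoking,Smoker,withdrawn,1.26,0.92,1.72
smoking,Smoker,lost,1.82,1.35,2.45
self_reported_health,Very good,dead,1.11,0.86,1.42
self_reported_health,Very good,frail,0.93,0.56,1.55
self_reported_health,Very good,withdrawn,0.98,0.73,1.33
self_reported_health,Very good,lost,1.10,0.79,1.53
self_reported_health,Good,dead,1.57,1.23,2.01
self_reported_health,Good,frail,1.58,0.97,2.55
self_reported_health,Good,withdrawn,1.11,0.83,1.49
self_reported_health,Good,lost,1.29,0.93,1.78
self_reported_health,Fair,dead,3.25,2.52,4.19
self_reported_health,Fair,frail,2.88,1.75,4.74
self_reported_health,Fair,withdrawn,1.41,1.03,1.93
self_reported_health,Fair,lost,1.94,1.37,2.73
self_reported_health,Poor,dead,11.87,7.92,17.79
self_reported_health,Poor,frail,7.14,3.54,14.41
self_reported_health,Poor,withdrawn,1.73,0.95,3.17
self_reported_health,Poor,lost,4.14,2.38,7.20
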