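indicator,2010,2011,2012,2013,2014,2015,2016
pct_female_caregivers,14.30,11.63,11.74,8.91,1.62,-4.48,3.86
pct_university_educated,7.46,3.63,5.72,4.62,8.67,9.09,8.20
pct_age_35_under,5.46,4.42,5.66,1.60,2.01,2.83,4.16
pct_age_36_55,-11.38,-13.33,-10.18,-11.60,-7.04,-4.70,-1.85
pct_age_56_over,15.34,18.69,15.03,10.93,9.20,7.10,2.77
pct_beneficiaries,-0.76,0.19,-0.35,-0.47,-1.40,-1.70,-1.64
pct_three_noes,-35.50,-31.63,-26.86,-50.22,-51.30,-52.10,-52.47
pct_self_financing,59.45,60.06,59.09,51.77,58.86,60.68,59.55
pct_fully_self_care,-14.05,-17.18,-9.05,-9.54,-13.66,-13.14,-11.75
pct_semi_self_care,0.16,3.40,3.39,1.26,3.86,4.36,5.29
pct_cannot_self_care,4.10,5.08,6.02,5.38,6.18,8.41,8.63
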