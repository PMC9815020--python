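area,indicator,2010,2011,2012,2013,2014,2015,2016
urban,n_institutions,5510,5645,6277,6915,7452,7474,8474
urban,floor_area,1074,1321,1533,1864,2269,2459,2869
urban,beds_year_end,57.67,63.60,74.16,99.23,106.45,116.84,131.08
urban,staff_year_end,7.50,8.07,9.18,10.55,11.92,12.80,14.46
urban,pct_female_caregivers,58.67,56.79,57.22,57.63,57.56,58.85,59.66
urban,pct_university_educated,16.54,15.09,16.26,20.48,22.80,24.69,24.99
urban,pct_age_35_under,25.53,25.32,26.37,26.75,26.59,26.39,25.65
urban,pct_age_36_55,51.69,48.78,53.00,56.70,58.51,60.75,64.24
urban,pct_age_56_over,22.78,25.90,20.63,16.75,15.81,13.38,10.11
urban,avg_days_in_care,237,247,248,243,239,239,236
urban,residents_year_end,36.49,38.73,42.83,96.77,56.80,58.59,65.06
urban,pct_beneficiaries,2.61,3.15,2.64,2.70,2.22,1.78,1.91
urban,pct_three_noes,31.97,31.55,30.55,21.98,24.44,20.84,19.67
urban,pct_self_financing,65.07,65.30,66.45,73.87,73.34,77.39,78.43
urban,pct_fully_self_care,62.24,56.93,61.27,62.66,58.08,57.13,57.80
urban,pct_semi_self_care,13.55,18.23,18.03,19.88,21.00,22.66,24.53
urban,pct_cannot_self_care,8.27,9.26,10.55,12.03,11.14,13.68,14.77
rural,n_institutions,28520,29100,29736,22523,19144,15081,14773
rural,floor_area,3155,4384,4798,3876,3366,2963,3135
rural,beds_year_end,209.21,226.11,244.68,206.39,209.72,167.69,168.06
rural,staff_year_end,13.19,14.29,14.89,14.32,12.42,10.46,10.64
rural,pct_female_caregivers,44.37,45.16,45.48,48.71,55.95,63.33,55.80
rural,pct_university_educated,9.08,11.46,10.54,15.85,14.13,15.61,16.79
rural,pct_age_35_under,20.07,20.90,20.71,25.15,24.58,23.55,21.49
rural,pct_age_36_55,63.07,62.11,63.18,68.30,65.55,65.45,66.10
rural,pct_age_56_over,7.44,7.21,5.60,5.83,6.61,6.28,7.34
rural,avg_days_in_care,226,255,267,261,253,249,246
rural,residents_year_end,169.12,179.12,186.33,137.47,144.57,106.71,103.73
rural,pct_beneficiaries,3.37,2.96,2.99,3.17,3.62,3.47,3.54
rural,pct_three_noes,67.47,63.18,57.41,72.20,75.74,72.94,72.14
rural,pct_self_financing,5.62,5.24,7.36,22.09,14.49,16.71,18.88
rural,pct_fully_self_care,76.29,74.11,70.32,72.20,71.74,70.27,69.55
rural,pct_semi_self_care,13.38,14.83,14.64,18.62,17.14,18.30,19.24
rural,pct_cannot_self_care,4.17,4.17,4.53,6.65,4.96,5.27,6.14
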