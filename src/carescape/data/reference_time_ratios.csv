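area,indicator,2010,2011,2012,2013,2014,2015,2016
urban,n_institutions,1.00,1.02,1.14,1.25,1.35,1.36,1.54
urban,floor_area,1.00,1.23,1.43,1.74,2.11,2.29,2.67
urban,beds_year_end,1.00,1.10,1.29,1.72,1.85,2.03,2.27
urban,staff_year_end,1.00,1.08,1.22,1.41,1.59,1.71,1.93
urban,avg_days_in_care,1.00,1.04,1.04,1.02,1.01,1.00,1.00
urban,residents_year_end,1.00,1.06,1.17,2.65,1.56,1.61,1.78
rural,n_institutions,1.00,1.02,1.04,0.79,0.67,0.53,0.52
rural,floor_area,1.00,1.39,1.52,1.23,1.07,0.94,0.99
rural,beds_year_end,1.00,1.08,1.17,0.99,1.00,0.80,0.80
rural,staff_year_end,1.00,1.08,1.13,1.09,0.94,0.79,0.81
rural,avg_days_in_care,1.00,1.13,1.18,1.15,1.12,1.10,1.09
rural,residents_year_end,1.00,1.06,1.10,0.81,0.85,0.63,0.61
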