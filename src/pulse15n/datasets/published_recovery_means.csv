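year,compartment,enrichment_mean,enrichment_se,recovery_pct_mean,recovery_pct_se
2007,current_year_shoots,135.72,25.42,1.69,0.41
2007,shoots_1_2yr,117.00,23.10,0.89,0.21
2007,litter_current,61.27,25.18,0.56,0.21
2007,moss,746.60,106.95,66.38,10.30
2007,O_horizon,24.38,4.03,17.80,2.98
2007,A_horizon,2.81,0.34,5.01,1.36
2007,B_horizon,0.46,0.22,0.43,0.24
2008,current_year_shoots,72.03,10.72,0.96,0.14
2008,shoots_1_2yr,62.69,11.54,0.44,0.08
2008,litter_current,43.21,10.10,0.62,0.14
2008,moss,544.87,56.34,42.08,5.92
2008,O_horizon,33.55,5.98,22.08,3.41
2008,A_horizon,5.15,1.00,7.05,1.46
2008,B_horizon,1.74,0.64,0.89,0.18
2009,current_year_shoots,54.44,5.91,0.74,0.08
2009,shoots_1_2yr,49.63,6.92,0.40,0.05
2009,litter_current,48.18,11.67,0.74,0.16
2009,moss,442.26,64.83,32.48,5.42
2009,O_horizon,35.61,5.78,22.55,3.10
2009,A_horizon,3.99,0.50,6.28,1.66
2009,B_horizon,1.66,0.62,0.96,0.29
2010,current_year_shoots,62.54,8.17,1.04,0.14
2010,shoots_1_2yr,54.18,6.62,0.48,0.07
2010,litter_current,46.51,9.01,0.88,0.17
2010,moss,346.97,33.39,24.44,2.73
2010,O_horizon,22.59,3.58,17.11,2.74
2010,A_horizon,4.72,1.11,8.08,2.68
2010,B_horizon,2.19,0.63,1.62,0.59
2011,current_year_shoots,57.85,5.64,0.94,0.10
2011,shoots_1_2yr,55.23,5.48,0.54,0.06
2011,litter_current,44.63,7.62,1.25,0.22
2011,moss,185.41,19.09,14.42,1.37
2011,O_horizon,29.86,2.47,24.27,2.59
2011,A_horizon,4.55,1.01,6.91,1.93
2011,B_horizon,1.57,0.43,0.94,0.19
2012,current_year_shoots,73.48,9.11,1.24,0.14
2012,shoots_1_2yr,67.00,7.97,0.62,0.09
2012,litter_current,38.03,6.85,0.94,0.16
2012,moss,149.50,13.27,10.76,1.35
2012,O_horizon,42.43,7.18,30.05,3.63
2012,A_horizon,6.39,1.05,8.43,1.94
2012,B_horizon,2.64,0.68,1.95,0.48
2013,current_year_shoots,56.05,6.37,0.91,0.10
2013,shoots_1_2yr,48.56,5.36,0.42,0.06
2013,litter_current,36.45,6.44,1.04,0.20
2013,moss,117.21,10.07,8.85,0.81
2013,O_horizon,33.12,3.44,24.52,3.14
2013,A_horizon,6.98,0.44,12.73,2.55
2013,B_horizon,2.02,0.58,1.63,0.37
2014,current_year_shoots,42.47,5.88,0.74,0.10
2014,shoots_1_2yr,38.91,4.97,0.33,0.05
2014,calluna_old,45.77,5.16,2.49,0.25
2014,calluna_roots,66.47,10.69,3.60,0.57
2014,litter_current,31.09,5.76,0.80,0.14
2014,moss,57.55,7.35,3.97,0.52
2014,O_horizon,50.61,7.69,36.11,6.02
2014,A_horizon,7.24,1.10,11.02,2.99
2014,B_horizon,1.89,0.43,1.39,0.58
2015,current_year_shoots,40.26,6.61,0.83,0.13
2015,shoots_1_2yr,39.47,5.64,0.41,0.07
2015,calluna_old,41.81,6.21,2.59,0.54
2015,calluna_roots,67.49,5.73,4.86,0.77
2015,litter_current,27.18,,0.93,0.15
2015,moss,46.97,7.11,2.91,0.46
2015,O_horizon,63.35,6.40,39.89,4.89
2015,A_horizon,5.19,1.07,6.61,1.46
2015,B_horizon,3.34,0.78,2.08,0.55
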