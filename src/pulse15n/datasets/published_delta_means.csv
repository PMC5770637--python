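year,compartment,delta_ref_mean,delta_ref_se,delta_lab_mean,delta_lab_se
2007,current_year_shoots,-5.67,0.51,129.30,25.56
2007,shoots_1_2yr,-5.92,0.47,110.42,23.28
2007,litter_current,-6.24,0.16,54.66,25.18
2007,moss,-6.19,0.22,735.74,106.17
2007,O_horizon,-4.53,0.35,19.74,4.22
2007,A_horizon,5.33,0.40,8.16,0.48
2007,B_horizon,8.71,0.43,8.74,0.69
2008,current_year_shoots,-6.54,0.69,65.00,10.43
2008,shoots_1_2yr,-7.67,0.63,54.54,11.40
2008,litter_current,-5.40,0.80,37.55,9.70
2008,moss,-5.93,0.38,535.65,55.71
2008,O_horizon,-4.79,0.44,28.60,6.03
2008,A_horizon,4.26,1.11,9.43,0.81
2008,B_horizon,7.16,1.32,8.90,0.76
2009,current_year_shoots,-6.90,0.52,47.15,5.53
2009,shoots_1_2yr,-7.68,0.57,41.55,6.46
2009,litter_current,-7.66,0.61,40.14,11.39
2009,moss,-6.60,0.31,432.63,63.96
2009,O_horizon,-4.85,0.48,30.62,4.92
2009,A_horizon,4.49,1.23,8.50,0.95
2009,B_horizon,6.73,1.36,8.30,1.00
2010,current_year_shoots,-6.85,0.56,55.23,7.56
2010,shoots_1_2yr,-7.96,0.51,45.77,6.13
2010,litter_current,-8.02,0.48,38.11,8.71
2010,moss,-6.11,0.34,338.70,32.94
2010,O_horizon,-3.99,0.59,18.57,2.91
2010,A_horizon,4.76,1.02,9.26,1.39
2010,B_horizon,7.68,1.11,9.82,1.03
2011,current_year_shoots,-6.02,0.46,51.47,5.23
2011,shoots_1_2yr,-7.50,0.42,47.30,5.14
2011,litter_current,-7.60,0.47,36.68,7.32
2011,moss,-6.32,0.49,177.92,18.88
2011,O_horizon,-4.50,0.42,25.12,2.17
2011,A_horizon,4.69,1.12,9.26,0.64
2011,B_horizon,7.21,1.25,8.78,1.01
2012,current_year_shoots,-6.30,0.51,66.69,8.60
2012,shoots_1_2yr,-7.07,0.46,59.44,7.55
2012,litter_current,-6.64,0.64,31.11,6.29
2012,moss,-6.79,0.18,141.69,13.06
2012,O_horizon,-3.52,0.53,38.77,7.28
2012,A_horizon,4.14,1.18,10.55,0.25
2012,B_horizon,6.62,1.28,10.24,0.46
2013,current_year_shoots,-6.55,0.50,49.12,6.05
2013,shoots_1_2yr,-7.58,0.44,40.61,5.05
2013,litter_current,-6.62,0.52,29.57,5.95
2013,moss,-6.75,0.35,109.67,9.92
2013,O_horizon,-3.58,0.63,29.41,2.84
2013,A_horizon,3.91,1.14,13.97,2.08
2013,B_horizon,7.14,1.10,10.22,0.30
2014,current_year_shoots,-6.06,0.56,36.13,5.51
2014,shoots_1_2yr,-6.72,0.50,31.92,4.72
2014,calluna_old,-7.00,0.46,38.44,4.85
2014,calluna_roots,-5.34,0.61,60.77,10.48
2014,litter_current,-6.78,0.43,24.09,5.36
2014,moss,-6.74,0.21,50.42,7.22
2014,O_horizon,-3.82,0.53,46.60,7.72
2014,A_horizon,3.53,1.01,15.63,3.97
2014,B_horizon,6.52,1.26,10.35,0.90
2015,current_year_shoots,-6.30,0.53,33.70,6.35
2015,shoots_1_2yr,-7.28,0.41,31.90,5.41
2015,calluna_old,-7.40,0.47,34.10,5.90
2015,calluna_roots,-5.39,0.52,61.74,5.87
2015,litter_current,-8.60,0.39,18.33,4.69
2015,moss,-6.63,0.24,40.02,6.87
2015,O_horizon,-3.78,0.55,59.32,6.17
2015,A_horizon,5.17,1.43,10.38,0.54
2015,B_horizon,6.13,1.08,9.48,0.47
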