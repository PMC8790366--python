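bird_id,sex,year,tracking_days,n_dives,dives_per_day,expenditure_kj,ted_kj,ted_per_day_kj,kiv_kj,needed_printed,pct_printed
D01,male,2017,4.91,113,23.06,17024,19763,4033,1005.04,19.66,17.4
D02,male,2017,2.86,36,12.56,8940,10538,3684,1005.04,10.48,29.13
D03,unknown,2017,5.08,189,37.15,15840,,,,,
D04,female,2017,0.97,65,66.89,3341,4154,4282,1005.96,4.13,6.35
D05,female,2017,1.83,39,21.31,6109,7643,4176,1005.96,7.6,19.48
D12,female,2017,4.68,90,19.19,16147,20070,4288,1005.96,19.95,22.17
D13,male,2017,4.72,87,18.44,14761,17399,3686,1005.04,17.31,19.9
D16,male,2017,1.99,18,9.06,6063,7175,3605,1005.04,7.14,39.66
D25,female,2018,3.04,37,12.17,10436,12984,4271,1563.34,8.31,22.45
D26,male,2018,2.92,36,12.31,11096,12728,4359,1552.61,8.2,22.77
D28,male,2018,4.61,230,49.84,14155,16731,3629,1552.61,10.78,4.68
D41,male,2018,4.83,39,8.07,15351,18051,3737,1552.61,11.63,29.81
D52,female,2018,4.32,42,9.72,13786,17408,4029,1563.34,11.14,26.51
D53,male,2018,5.05,25,4.95,16375,19198,3801,1552.61,12.37,49.46
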