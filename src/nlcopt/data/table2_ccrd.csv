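run_id,X1_wt_pct,X2_pct_total_lipid,X3_wt_pct,X4_wt_pct,Y1_nm_mean,Y1_nm_sd,Y2_pdi_mean,Y2_pdi_sd,Y3_mV_mean,Y3_mV_sd,Y4_ee_pct_mean,Y4_ee_pct_sd,n_replicates
1,6.75,30.00,6.50,1.38,59.25,0.73,0.17,0.02,-11.93,2.24,75.83,5.54,3
2,6.75,30.00,3.50,1.38,99.98,1.64,0.17,0.01,-10.48,2.64,78.31,1.17,3
3,6.75,30.00,3.50,0.13,99.29,1.27,0.18,0.03,-10.05,0.60,69.10,4.13,3
4,3.50,15.00,2.00,0.75,111.13,2.53,0.22,0.02,-11.16,1.23,56.80,7.85,3
5,6.75,30.00,3.50,2.63,104.00,1.63,0.19,0.02,-12.70,0.93,58.44,1.78,3
6,0.25,30.00,3.50,1.38,76.48,4.37,0.41,0.27,-14.89,3.40,67.80,0.14,3
7,6.75,30.00,0.50,1.38,489.33,5.92,0.45,0.21,-14.79,1.49,65.64,3.94,3
8,10.00,15.00,5.00,2.00,151.43,2.37,0.27,0.01,-6.68,4.49,40.30,1.88,3
9,13.25,30.00,3.50,1.38,240.00,7.39,0.26,0.06,-9.85,0.35,57.63,0.41,3
10,6.75,30.00,3.50,1.38,111.20,5.88,0.18,0.03,-10.89,3.67,77.91,4.18,3
11,6.75,30.00,3.50,1.38,106.11,7.14,0.18,0.02,-10.72,1.45,76.38,1.79,3
12,6.75,30.00,3.50,1.38,95.76,5.29,0.18,0.02,-10.07,2.65,77.31,1.87,3
13,10.00,45.00,5.00,0.75,120.57,2.07,0.21,0.02,-6.16,1.65,64.04,2.21,3
14,3.50,15.00,2.00,2.00,120.50,1.85,0.30,0.06,-12.95,1.84,51.82,3.99,3
15,10.00,45.00,2.00,2.00,243.00,4.28,0.19,0.05,-12.73,1.21,62.22,1.65,3
16,10.00,45.00,5.00,2.00,117.00,2.14,0.03,0.00,-10.70,3.22,65.61,5.39,3
17,10.00,15.00,5.00,0.75,121.39,1.74,0.23,0.01,-5.76,1.79,45.13,3.01,3
18,3.50,45.00,5.00,0.75,53.25,1.13,0.23,0.03,-8.58,2.68,73.28,1.97,3
19,10.00,15.00,2.00,0.75,459.25,19.70,0.33,0.13,-12.71,2.69,66.91,7.10,3
20,6.75,30.00,3.50,1.38,99.76,1.78,0.17,0.03,-10.69,1.45,75.78,5.18,3
21,10.00,15.00,2.00,2.00,456.00,12.88,0.34,0.09,-12.01,1.86,59.71,7.72,3
22,3.50,15.00,5.00,2.00,76.48,1.26,0.42,0.02,-7.99,2.00,77.66,1.20,3
23,6.75,0.00,3.50,1.38,147.00,2.27,0.26,0.01,-10.85,0.53,66.06,4.79,3
24,3.50,45.00,2.00,2.00,82.21,1.05,0.18,0.02,-15.06,1.67,77.70,4.50,3
25,10.00,45.00,2.00,0.75,235.29,4.35,0.19,0.04,-8.02,3.93,59.61,1.38,3
26,3.50,15.00,5.00,0.75,88.85,1.28,0.36,0.03,-7.71,0.92,63.80,5.41,3
27,3.50,45.00,2.00,0.75,90.94,1.56,0.20,0.02,-12.94,0.69,74.39,5.91,3
28,3.50,45.00,5.00,2.00,57.68,1.39,0.27,0.04,-10.62,1.20,77.62,5.40,3
29,6.75,30.00,3.50,1.38,96.78,3.05,0.16,0.09,-10.87,1.84,80.76,3.12,3
30,6.75,60.00,3.50,1.38,124.13,3.52,0.19,0.02,-13.58,1.33,66.90,1.60,3
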