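run_order,pH_actual,temperature_actual,diesel_actual,NaCl_actual,experimental,predicted
1,7.25,40.00,2.50,1.00,18.26,25.81
2,8.00,30.00,4.00,2.00,17.05,18.66
3,7.25,20.00,2.50,-1.00,95.67,91.93
4,7.25,20.00,2.50,1.00,93.34,88.76
5,7.25,20.00,2.50,1.00,93.01,88.76
6,8.75,20.00,2.50,1.00,37.27,41.80
7,8.00,10.00,1.00,0.00,14.16,15.72
8,8.00,10.00,4.00,2.00,3.61,6.12
9,8.00,30.00,1.00,0.00,57.00,51.69
10,7.25,20.00,2.50,1.00,90.12,88.76
11,7.25,20.00,2.50,1.00,87.67,88.76
12,7.25,0.00,2.50,1.00,0.70,-6.23
13,5.75,20.00,2.50,1.00,70.00,66.09
14,6.50,10.00,4.00,0.00,34.34,43.74
15,6.50,30.00,1.00,0.00,69.27,67.24
16,8.00,30.00,4.00,0.00,71.50,72.04
17,6.50,10.00,4.00,2.00,10.63,14.85
18,7.25,20.00,2.50,1.00,87.45,88.76
19,6.50,10.00,1.00,0.00,50.46,47.75
20,7.25,20.00,5.50,1.00,21.71,10.11
21,6.50,30.00,4.00,0.00,76.81,79.80
22,6.50,30.00,4.00,2.00,12.01,10.92
23,8.00,30.00,1.00,2.00,25.70,16.78
24,8.00,10.00,1.00,2.00,24.89,20.80
25,6.50,30.00,1.00,2.00,20.35,16.83
26,8.00,10.00,4.00,0.00,17.09,19.50
27,7.25,20.00,2.50,3.00,23.78,28.13
28,7.25,20.00,2.50,1.00,81.00,88.76
29,7.25,20.00,-0.50,1.00,0.00,12.23
30,6.50,10.00,1.00,2.00,37.38,37.32
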