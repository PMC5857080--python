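run_order,pH_actual,temperature_actual,diesel_actual,NaCl_actual,experimental,predicted
1,7.25,40.00,2.50,1.00,0.83,4.86
2,8.00,30.00,4.00,2.00,0.71,0.82
3,7.25,20.00,2.50,-1.00,34.77,32.88
4,7.25,20.00,2.50,1.00,33.34,30.73
5,7.25,20.00,2.50,1.00,32.01,30.73
6,8.75,20.00,2.50,1.00,17.27,16.70
7,8.00,10.00,1.00,0.00,14.42,12.79
8,8.00,10.00,4.00,2.00,0.04,0.99
9,8.00,30.00,1.00,0.00,26.50,24.43
10,7.25,20.00,2.50,1.00,31.67,30.73
11,7.25,20.00,2.50,1.00,30.45,30.73
12,7.25,0.00,2.50,1.00,0.01,-3.17
13,5.75,20.00,2.50,1.00,20.00,21.42
14,6.50,10.00,4.00,0.00,4.34,6.22
15,6.50,30.00,1.00,0.00,29.81,26.77
16,8.00,30.00,4.00,0.00,19.00,21.46
17,6.50,10.00,4.00,2.00,0.06,3.37
18,7.25,20.00,2.50,1.00,30.12,30.73
19,6.50,10.00,1.00,0.00,17.46,18.57
20,7.25,20.00,5.50,1.00,1.71,-4.94
21,6.50,30.00,4.00,0.00,19.27,19.77
22,6.50,30.00,4.00,2.00,0.23,-0.23
23,8.00,30.00,1.00,2.00,4.89,0.92
24,8.00,10.00,1.00,2.00,5.70,6.43
25,6.50,30.00,1.00,2.00,6.35,3.89
26,8.00,10.00,4.00,0.00,0.80,4.48
27,7.25,20.00,2.50,3.00,3.78,6.51
28,7.25,20.00,2.50,1.00,26.83,30.73
29,7.25,20.00,-0.50,1.00,0.00,7.50
30,6.50,10.00,1.00,2.00,17.38,12.84
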