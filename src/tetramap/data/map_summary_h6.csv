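lg,n_markers,length_cm,avg_spacing_cm,max_spacing_cm,avg_aa,avg_ab,ab_aa_ratio
1A,38,257.5,6.96,40.72,17.97,68.63,3.82
1B,22,124.6,5.94,16.66,26.73,60.68,2.27
1C,31,172.9,5.76,21.01,34.23,50.77,1.48
1D,18,166.6,9.80,28.76,70.06,14.83,0.21
2A,48,266.3,5.67,18.33,12.90,73.10,5.67
2B,11,93.6,9.36,17.29,31.91,52.00,1.63
2C,22,173.5,8.26,32.11,67.45,14.82,0.22
3A,52,344.7,6.76,17.23,17.38,68.38,3.93
3B,30,147.8,5.10,15.71,19.37,65.63,3.39
3C,7,34.3,5.71,11.11,42.43,44.14,1.04
3D,5,26.6,6.65,9.12,45.00,42.80,0.95
3E,33,225.0,7.03,17.26,67.21,17.24,0.26
4A,15,148.7,10.62,19.71,15.33,66.47,4.33
4B,42,289.9,7.07,17.61,23.71,62.60,2.64
4C,13,138.7,11.56,33.11,51.62,29.92,0.58
4D,38,327.7,8.86,24.14,63.89,17.08,0.27
5A,5,59.6,14.89,18.80,11.00,72.20,6.56
5B,16,78.1,5.21,14.50,49.13,34.31,0.70
5C,19,135.6,7.53,22.71,76.16,15.21,0.20
6A,27,215.4,8.28,23.06,30.00,57.19,1.91
6B,17,142.9,8.93,19.86,38.24,47.59,1.24
6C,7,59.6,9.93,13.65,39.00,48.29,1.24
6D,27,264.9,10.19,27.41,60.56,22.22,0.37
7A,24,182.5,7.93,16.07,12.96,72.92,5.63
7B,4,30.5,10.18,13.25,34.25,57.00,1.66
7C,3,19.5,9.75,16.09,30.67,45.33,1.48
7D,26,223.5,8.94,20.07,54.58,25.50,0.47
8A,31,269.2,8.97,26.05,12.84,68.29,5.32
8B,22,299.0,14.24,29.05,48.23,29.50,0.61
9A,34,231.7,7.02,22.51,14.00,67.50,4.82
9B,13,95.5,7.96,16.56,35.77,47.15,1.32
9C,32,260.0,8.39,30.14,63.78,17.38,0.27
10A,20,126.7,6.67,19.38,21.35,67.10,3.14
10B,19,250.6,13.92,48.90,34.89,50.74,1.45
10C,24,165.3,7.19,36.34,65.00,21.29,0.33
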