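lg,n_markers,length_cm,avg_spacing_cm,max_spacing_cm,avg_aa,avg_ab,ab_aa_ratio
1A,49,271.1,5.65,34.45,24.63,94.61,3.84
1B,16,74.8,4.98,18.95,42.94,74.31,1.73
1C,9,35.9,4.49,7.08,47.11,77.11,1.64
1D,5,10.8,2.71,3.14,56.40,52.00,0.92
1E,20,110.6,5.82,27.36,95.15,27.10,0.28
2A,11,63.4,6.34,32.51,23.55,89.55,3.80
2B,19,39.3,2.18,8.04,33.74,85.74,2.54
2C,22,91.7,4.37,14.18,52.32,64.41,1.23
2D,47,164.2,3.57,18.09,89.04,29.28,0.33
3A,31,146.8,4.89,27.67,28.94,88.65,3.06
3B,35,166.7,4.90,22.33,45.43,72.17,1.59
3C,22,182.3,8.68,42.99,60.59,60.18,0.99
3D,33,112.0,3.50,14.36,82.73,34.27,0.41
4A,29,208.8,7.46,24.88,25.62,89.93,3.51
4B,9,67.7,8.47,24.43,46.00,69.89,1.52
4C,18,198.8,11.69,56.32,56.56,57.50,1.02
4D,29,149.6,5.34,19.48,81.14,36.66,0.45
5A,4,17.1,5.71,9.65,39.75,86.25,2.17
5B,7,37.8,6.30,16.42,62.71,55.57,0.89
5C,21,121.0,6.05,21.07,87.19,33.67,0.39
6A,26,99.3,3.97,11.20,30.35,88.35,2.91
6B,23,135.4,6.16,21.14,44.26,75.13,1.70
6C,11,61.6,6.16,15.65,80.36,33.91,0.42
7A,24,236.0,10.26,38.84,27.04,90.29,3.34
7B,5,9.6,2.40,5.68,58.20,67.20,1.15
7C,25,101.6,4.23,9.91,58.60,56.68,0.97
7D,11,41.2,4.12,11.96,84.82,33.36,0.39
8A,12,110.5,10.05,26.00,24.50,92.50,3.78
8B,7,46.7,7.78,12.20,44.43,65.86,1.48
8C,4,22.0,7.33,8.39,53.50,63.00,1.18
8D,8,23.6,3.37,6.89,94.13,25.25,0.27
9A,13,121.7,10.14,32.60,20.92,92.15,4.40
9B,26,98.2,3.93,18.93,86.50,31.27,0.36
10A,15,79.9,5.71,24.93,24.20,92.80,3.83
10B,7,40.2,6.70,14.01,49.14,67.57,1.38
10C,35,248.9,7.32,18.81,62.91,59.29,0.94
10D,34,149.6,4.53,23.21,88.74,28.82,0.32
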