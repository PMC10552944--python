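group,gender,age,ados_total,ados_sa,ados_rrb,severity,mullen_vr_dq,mullen_vr_raw,mullen_vr_t,mullen_fm_dq,mullen_fm_raw,mullen_fm_t,mullen_el_dq,mullen_el_raw,mullen_el_t,mullen_rl_dq,mullen_rl_raw,mullen_rl_t,vineland_rl,vineland_el
ASD,M,2.54,7,6,7,moderate,96.15,31,47,96.15,29,46,73.72,22,35,96.15,28,46,15,14
ASD,F,3.29,10,9,10,high,17.73,10,20,32.92,15,20,5.07,3,20,10.13,6,20,5,3
ASD,M,1.74,5,6,5,moderate,82.63,19,36,82.63,18,34,46.48,10,21,67.13,14,26,10,13
ASD,M,2.76,10,9,10,high,90.75,25,34,77.3,22,20,50.41,15,24,53.78,15,20,10,8
ASD,F,2.25,7,8,5,moderate,92.6,28,46,74.8,22,29,60.55,17,30,60.55,18,26,12,14
ASD,M,2.93,10,7,10,high,68.1,26,24,62.42,23,20,11.35,7,20,17.02,6,20,9,7
ASD,M,1.99,10,8,10,high,99.86,26,49,95.7,24,48,58.25,14,28,20.8,7,20,9,7
ASD,M,3.5,10,8,10,high,65.1,27,22,67.71,26,20,41.67,16,20,28.65,13,20,9,9
ASD,M,4.18,8,7,10,high,118.97,48,63,113.02,45,63,71.38,32,32,77.33,34,36,10,15
ASD,M,2.37,10,9,10,high,66.35,22,29,59.37,19,20,31.43,10,20,13.97,6,20,9,8
ASD,F,4.73,9,7,10,high,100.22,47,52,86.15,41,39,101.97,45,52,114.28,47,62,13,17
ASD,F,3.07,10,7,10,high,40.45,18,20,45.84,19,20,16.18,7,20,18.88,9,20,6,5
ASD,M,2.69,6,6,6,moderate,80.53,28,39,71.24,24,26,40.27,13,20,43.36,15,20,9,10
ASD,M,3.01,6,4,10,moderate,71.44,28,31,76.93,28,35,71.44,24,33,65.94,24,30,11,13
ASD,M,2.26,9,10,6,high,93.3,18,43,105.74,19,53,24.88,5,20,68.42,13,31,12,15
ASD,F,2.73,8,6,10,high,76.04,27,36,85.17,28,42,36.5,12,20,27.38,11,20,10,13
ASD,M,3.29,6,6,9,moderate,83.65,33,40,76.04,29,32,55.76,21,22,63.37,25,27,10,10
ASD,M,3.35,8,7,10,high,111.73,41,55,84.42,32,36,89.39,32,43,81.94,30,38,13,8
ASD,M,2.01,7,6,9,moderate,97.46,26,49,113.71,28,64,60.91,15,30,97.46,24,50,11,10
ASD,M,4.77,9,10,6,high,103.75,48,55,98.56,45,51,95.11,44,49,81.27,39,39,13,13
ASD,M,4.48,7,7,8,moderate,83.72,41,37,115.34,47,65,78.13,36,37,85.58,38,41,13,14
ASD,M,2.72,6,4,9,moderate,88.74,30,44,85.68,28,42,82.62,25,41,76.5,25,38,12,13
ASD,F,2.05,9,10,7,high,55.23,16,20,72.22,19,24,29.74,8,20,21.24,7,20,9,6
ASD,M,3.64,6,5,10,moderate,130.55,47,69,96.2,37,46,125.97,44,64,107.65,39,54,19,15
ASD,M,2.66,4,3,8,low,105.25,31,56,91.21,26,45,77.18,21,39,80.69,23,39,14,16
ASD,M,2.45,9,9,6,high,/,/,/,/,/,/,/,/,/,/,/,/,11,9
ASD,M,4.11,10,10,9,high,54.24,29,20,52.23,26,20,24.11,12,20,32.14,17,20,8,8
ASD,M,3.86,6,5,9,moderate,147.49,50,80,121.84,45,69,123.98,45,63,126.11,45,65,15,14
ASD,M,1.99,7,9,5,moderate,103.78,28,52,63.87,18,20,31.93,9,20,43.91,13,20,11,10
ASD,M,3.3,7,7,8,moderate,77.8,32,37,67.76,27,23,45.17,18,20,70.27,27,34,9,9
ASD,M,5.14,4,4,7,low,111.81,50,61,100.47,47,54,93.99,45,48,111.81,48,63,14,13
TD,M,1.98,1,1,1,/,102.62,27,53,90.31,23,44,73.89,18,38,82.1,21,40,16,15
TD,M,2.9,1,1,5,/,117.98,/,/,106.47,/,/,123.74,/,/,106.47,/,/,16,15
TD,M,4.15,1,1,5,/,131.99,49,68,97.99,41,48,119.99,46,62,123.99,46,65,17,22
TD,M,2.29,1,1,1,/,214.71,48,80,121.67,32,68,153.87,37,75,150.29,36,74,18,16
TD,M,2.22,1,1,1,/,123.01,33,61,104.37,28,53,134.19,32,66,123.01,30,59,19,19
TD,F,2.65,1,1,5,/,141.25,41,72,103.59,31,53,131.84,36,67,128.7,35,65,18,16
TD,F,1.34,1,1,1,/,180.75,30,80,112.19,20,49,124.66,19,54,155.82,25,69,17,15
TD,M,1.73,1,1,1,/,144.15,31,79,86.49,20,43,129.74,25,68,144.15,28,72,19,17
TD,M,3.12,1,1,1,/,144.84,46,75,91.2,32,42,123.38,39,62,109.97,35,54,17,21
TD,M,1.8,1,1,1,/,115.92,27,58,120.55,26,62,69.55,15,33,88.1,20,42,13,15
TD,F,1.8,2,2,1,/,125.19,29,64,120.55,26,62,69.55,15,33,115.92,25,58,9,15
TD,M,5.44,1,1,1,/,101.18,49,48,104.25,49,53,102.72,48,51,105.78,48,54,15,16
TD,M,2.34,1,1,6,/,103.29,30,53,92.6,26,45,124.66,31,64,117.54,30,59,17,17
TD,M,2,1,1,1,/,/,/,/,/,/,/,/,/,/,/,/,/,14,16
TD,F,2.19,1,1,1,/,/,/,/,/,/,/,/,/,/,/,/,/,16,16
TD,M,2.67,1,1,1,/,109.5,35,58,100.38,31,53,109.5,32,58,139.92,38,70,17,18
TD,M,4.76,1,1,1,/,/,/,/,/,/,/,/,/,/,/,/,/,17,21
TD,M,1.7,1,1,1,/,/,/,/,/,/,/,/,/,/,/,/,/,16,14
TD,M,5.33,1,1,1,/,107.02,50,69,79.11,42,46,108.58,50,75,96.17,46,61,17,18
TD,M,3.14,1,1,5,/,112.27,40,58,109.66,37,59,117.49,38,60,122.71,39,63,17,16
TD,M,5.1,1,1,1,/,114.94,50,58,113.27,49,58,96.61,45,45,98.28,45,46,16,20
TD,F,2.73,1,1,5,/,/,/,/,/,/,/,/,/,/,/,/,/,17,14
TD,M,5.56,1,1,1,/,98.84,49,48,101.84,49,53,79.37,43,39,92.85,46,44,17,19
TD,M,3.82,1,2,1,/,143.91,49,79,115.56,43,68,/,/,/,124.28,44,67,17,19
TD,F,1.57,1,1,1,/,92.02,21,48,102.24,21,54,71.57,14,37,122.69,24,67,12,15
TD,F,1.31,1,1,1,/,104.89,20,53,92.55,17,42,129.56,20,66,117.22,20,60,17,17
TD,F,2.73,1,1,1,/,123.6,39,66,93.45,30,49,87.42,27,46,117.57,34,62,20,17
TD,M,4.68,1,1,1,/,116.92,49,60,93.89,43,45,93.89,43,46,97.43,43,48,18,18
TD,F,1.87,1,1,1,/,138.26,32,75,120.42,27,66,75.82,17,39,124.88,27,65,15,19
TD,M,2.23,1,1,5,/,107.61,31,56,96.85,27,48,82.5,22,41,107.61,28,53,15,15
TD,M,1.68,1,1,1,/,172.07,34,80,121.46,25,64,86.04,17,43,151.83,28,72,15,17
TD,F,3.13,1,1,5,/,127.73,43,65,87.82,31,39,87.82,33,49,109.11,35,54,15,20
TD,F,4.33,1,1,1,/,115.07,48,59,109.32,45,56,120.82,47,61,118.91,46,61,18,18
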