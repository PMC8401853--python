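run_id,lecithin_mg,chitosan_mg,ipm_pct,PS_mean,PS_sd,ZP_mean,ZP_sd,EE_mean,EE_sd
1,150,10,1,116.4,5.33,19.1,0.3,43.32,3.4
2,150,25,2,175.0,10.4,28.3,1.3,72.79,5.2
3,100,10,2,125.4,7.95,21.7,0.9,67.21,4.2
4,200,25,3,196.4,11.3,27.9,1.7,82.37,6.2
5,150,40,3,242.1,12.3,34.8,2.3,84.97,4.9
6,200,40,2,219.2,7.14,31.2,1.9,77.36,2.7
7,150,25,2,178.6,8.26,29.6,2.4,73.44,4.3
8,100,25,1,171.3,6.41,31.5,2.8,46.74,3.9
9,150,40,1,211.1,9.79,35.1,3.2,53.37,4.7
10,200,25,1,173.8,10.6,27.1,2.4,48.93,2.5
11,200,10,2,141.9,5.23,18.5,0.6,69.53,3.6
12,150,10,3,157.7,4.62,19.7,1.2,79.39,5.1
13,100,40,2,216.8,13.1,36.8,2.7,75.71,4.5
14,100,25,3,184.9,5.84,30.7,2.5,81.52,3.7
15,150,25,2,180.0,4.92,27.8,1.6,74.37,6.3
16,150,25,2,168.4,3.47,28.8,2.3,71.73,3.1
17,150,25,2,173.5,6.28,30.0,2.9,70.95,4.6
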