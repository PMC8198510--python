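chrom_id,mbp,gene_density,canonical_ci,group
1,248.9,8.27,49.6,A
2,242.2,5.40,38.8,A
3,198.3,5.44,45.8,A
4,190.2,3.95,26.3,B
5,181.5,4.83,26.9,B
6,170.8,6.14,35.0,C
7,159.3,6.21,37.7,C
8,145.1,4.67,31.2,C
9,138.4,5.68,31.1,C
10,133.8,5.48,29.7,C
11,135.1,9.61,39.5,C
12,133.3,7.76,26.6,C
13,114.4,2.86,16.0,D
14,107.0,7.76,16.5,D
15,102.0,6.01,17.0,D
16,90.3,9.67,40.8,E
17,83.3,14.37,30.1,E
18,80.4,3.36,23.0,E
19,58.6,25.12,44.7,F
20,64.4,8.45,43.6,F
21,46.7,5.01,16.0,G
22,50.8,9.61,16.5,G
X,156.0,5.40,39.1,H
Y,57.2,1.24,17.0,H
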