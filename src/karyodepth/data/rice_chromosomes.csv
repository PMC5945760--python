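chrom,length,centromere,gene_count,link_count
1,43270923,16700000,,
2,35937250,13600000,,
3,36413819,19400000,,
4,35502694,9700000,,
5,29958434,12400000,,
6,31248787,15300000,,
7,29697621,12100000,,
8,28443022,12900000,,
9,23012720,2800000,,
10,23207287,8200000,,
11,29021106,12000000,,
12,27531856,11900000,,
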