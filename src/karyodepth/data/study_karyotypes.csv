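karyotype_id,karyotype_string,n_plants
#1,+ 1 Chr. 01,1
#2,- 1 Chr. 02,1
#3,+ 1 Chr. 02,3
#4,- 1 Chr. 03,1
#5,- 1 Chr. 04,8
#6,+ 1 Chr. 04,4
#7,- 1 Chr. 05,1
#8,+ 1 Chr. 05,5
#9,- 1 Chr. 06,4
#10,+ 1 Chr. 06,1
#11,- 1 Chr. 07,3
#12,+ 1 Chr. 07,5
#13,+ 1 Chr. 08,2
#14,- 1 Chr. 09,6
#15,+ 1 Chr. 09,10
#16,- 1 Chr. 10,5
#17,+ 1 Chr. 10,5
#18,- 1 Chr. 11,1
#19,+ 1 Chr. 11,10
#20,- 1 Chr. 12,5
#21,+ 1 Chr. 12,3
#22,+2 Chr. 10,1
#23,+2S Chr. 10,1
#24,+2 Chr. 11,2
#25,- 1L Chr. 11,2
#26,+ 1S Chr. 11,1
#27,+2 Chr. 12,1
#28,+ 1 Chr. 01; + 1 Chr. 09,1
#29,+ 1 Chr. 01; - 1 Chr. 10,1
#30,+ 1 Chr. 02; + 1 Chr. 06,1
#31,- 1 Chr. 02; + 1 Chr. 04,1
#32,- 1 Chr. 02; + 1 Chr. 05,1
#33,+ 1 Chr. 03; + 1 Chr. 04,1
#34,+ 1 Chr. 04; - 1 Chr. 08,1
#35,+ 1 Chr. 04; - 1 Chr. 09,1
#36,+ 1 Chr. 04; + 1 Chr. 11,3
#37,- 1 Chr. 04; + 1 Chr. 08,1
#38,- 1 Chr. 04; + 1 Chr. 11,1
#39,+ 1 Chr. 05; + 1 Chr. 06,2
#40,+ 1 Chr. 07; + 1 Chr. 10,1
#41,+ 1 Chr. 07; - 1 Chr. 10,1
#42,+ 1 Chr. 07; + 1 Chr. 11,1
#43,+ 1 Chr. 08; + 1 Chr. 09,1
#44,+ 1 Chr. 08; + 1 Chr. 12,1
#45,+ 1 Chr. 09; + 1 Chr. 11,1
#46,+ 1 Chr. 10; + 1 Chr. 12,1
#47,- 1 Chr. 10; + 1 Chr. 11,1
#48,+2L Chr. 05; + 1 Chr. 09,2
#49,+2 Chr. 09; - 1 Chr. 12,1
#50,-2 Chr. 09; + 1 Chr. 11,1
#51,+ 1 Chr. 04; + 1 Chr. 07; + 1 Chr. 11,1
#52,- 1 Chr. 04; + 1 Chr. 06; + 1 Chr. 11,1
#53,+ 1 Chr. 05; + 1 Chr. 08; - 1 Chr. 12,1
#54,- 1S Chr. 04; +2S Chr. 11; - 1L Chr. 11,1
#55,- 1L Chr. 01; + 1/2S Chr. 01; - 1L Chr. 06; - 1L Chr. 12,1
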