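date,phase,impressions,clicks,views
2016-08-04,0,4639,198,102
2016-08-05,0,8831,346,200
2016-08-06,0,11058,412,204
2016-08-07,0,14731,544,290
2016-08-08,0,24697,699,272
2016-08-09,0,28165,563,237
2016-08-10,0,31336,778,242
2016-08-11,0,23904,602,172
2016-08-12,0,21661,578,172
2016-08-13,0,17584,501,167
2016-08-14,0,16884,417,124
2016-08-15,0,22518,585,198
2016-08-16,0,20854,523,188
2016-08-17,0,19964,458,168
2016-08-18,0,18252,435,161
2016-08-19,0,15264,353,126
2016-08-20,0,16552,381,168
2016-08-21,0,17594,392,148
2016-08-22,0,15061,528,138
2016-08-23,0,22975,784,228
2016-08-24,1,53280,2708,825
2016-08-25,1,54076,3154,1007
2016-08-26,1,47259,2778,819
2016-08-27,1,55165,3067,898
2016-08-28,1,67832,3882,1485
2016-08-29,1,72089,4243,1664
2016-08-30,1,79789,4679,1721
2016-08-31,1,88074,4967,2041
2016-09-01,1,96850,5118,2118
2016-09-02,1,88455,4770,1975
2016-09-03,1,99190,4545,1643
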