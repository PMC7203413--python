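chrom	lg_h4	lg_h6	h4_start	h4_end	h6_start	h6_end
1	1A	1A	1002293	2075903	1002293	2075903
1		1A			4118965	5421700
1	1A	1A	9156903	9747197	9156903	9747197
1	1A	1A	10172236	11113096	10172236	11113096
1	1A		58398011	60856958
1		1B			60795489	61898805
1		1C			68343440	69007210
2		2A			37375688	49746108
2	2B		70855137	71665944
2		2A			72907102	73093086
3	3A	3A	7974628	10505659	7974628	10505659
3		3A			57155624	57669990
3		3A			66256314	66512680
3	3B		57050572	57258601
3	3B	3A	71350072	73236656	72084184	73236656
3		3E			5529567	7162059
3	3C		8639654	60878509
4	4A	4B	60169823	66355590	58910354	64899883
4	4B		64423184	64876657
4	4D		61407366	64036600
6	6A	6A	55862094	64036600	55862094	57182238
6	6A	6A	55862094	64036600	58155004	58738149
6	6B	6B	3622183	37245941	3327280	37245941
9	9A		57335220	58856483
9		9A			55778912	57267091
10		10B			52116222	59317021
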