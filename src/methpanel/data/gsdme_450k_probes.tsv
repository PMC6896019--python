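probe_index	illumina_name	coordinate	region	chromosome
1	CpG17790129	24738572	Gene body	7
2	CpG14205998	24748668	Gene body	7
3	CpG04317854	24762562	Gene body	7
4	CpG12922093	24767644	Gene body	7
5	CpG17569154	24781545	Gene body	7
6	CpG19260663	24791121	Gene body	7
7	CpG09333471	24796355	Putative Promoter	7
8	CpG00473134	24796494	Putative Promoter	7
9	CpG03995857	24796553	Putative Promoter	7
10	CpG07320646	24796981	Putative Promoter	7
11	CpG07293520	24797192	Putative Promoter	7
12	CpG04770504	24797363	Putative Promoter	7
13	CpG24805239	24797486	Putative Promoter	7
14	CpG01733570	24797656	Putative Promoter	7
15	CpG25723149	24797680	Putative Promoter	7
16	CpG22804000	24797691	Putative Promoter	7
17	CpG07504598	24797786	Putative Promoter	7
18	CpG15037663	24797835	Putative Promoter	7
19	CpG19706795	24797839	Putative Promoter	7
20	CpG20764575	24797884	Putative Promoter	7
21	CpG06301139	24798175	Upstream Region	7
22	CpG26712096	24798855	Upstream Region	7
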