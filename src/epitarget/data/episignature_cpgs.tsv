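locus	probe_id	chrom	position	delta_beta
1.1	cg12242450	chr6	10555808	-0.2091863895
1.1	cg13347910	chr6	10555853	-0.1895768459
1.1	cg20812045	chr6	10555881	-0.2185013189
1.1		chr6	10555905
1.2	cg05869816	chr6	10556107	-0.2050925327
1.2	cg12695465	chr6	10556147	-0.2022041231
1.2		chr6	10556052
1.2		chr6	10556069
1.2		chr6	10556098
1.2		chr6	10556174
1.2		chr6	10556199
1.2		chr6	10556204
1.2		chr6	10556244
2.1	cg04088940	chr2	206628454	-0.1900411119
2.1	cg22308949	chr2	206628553	-0.1705186729
2.1		chr2	206628415
2.1		chr2	206628484
2.1		chr2	206628491
2.1		chr2	206628521
2.1		chr2	206628525
2.1		chr2	206628529
2.1		chr2	206628531
2.1		chr2	206628539
2.2	cg05348875	chr2	206628625	-0.2226405291
2.2	cg14157435	chr2	206628692	-0.2487043485
2.2	cg10126788	chr2	206628727	-0.2404856455
2.2	cg20351668	chr2	206628737	-0.2675453596
2.2	cg25715429	chr2	206628747	-0.2529336105
2.2	cg10807027	chr2	206628773	-0.2044400041
2.2		chr2	206628592
2.2		chr2	206628606
2.2		chr2	206628609
2.2		chr2	206628621
2.2		chr2	206628645
2.2		chr2	206628714
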