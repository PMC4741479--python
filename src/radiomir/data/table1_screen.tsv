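mirna_id	fc_wt	sd_wt	fc_null	sd_null
hsa-let-7e	0.89194	0.0388	1.42886	0.0335
hsa-let-7f	1.03497	0.1200	1.62202	0.0341
hsa-let-7g	1.20312	0.0359	1.07888	0.0470
hsa-mir-016	0.88144	0.1411	2.24896	0.1462
hsa-mir-019a	0.89458	0.0141	0.91168	0.0298
hsa-mir-019b	0.88981	0.0490	0.9242	0.0610
hsa-mir-020a	1.19119	0.1565	0.82158	0.1914
hsa-mir-027a	0.97308	0.0415	1.40207	0.0356
hsa-mir-029b	0.78003	0.0145	1.56938	0.1775
hsa-mir-029c	1.07076	0.1039	1.20673	0.1883
hsa-mir-030c	0.55318	0.0699	1.60287	0.1257
hsa-mir-030e 3p	1.05512	0.0711	0	0
hsa-mir-101	0.92582	0.0323	0.73823	0.0517
hsa-mir-106a	0.80357	0.0579	1.92872	0.0678
hsa-miR-1248	2.2929	0.1513	0	0
hsa-miR-1254	0.75457	0.0154	0	0
hsa-miR-1308	0.85653	0.0533	1.06383	0.0970
hsa-mir-142 3p	0.79681	0.0180	0.83335	0.1186
hsa-mir-150	1.14678	0.0265	0	0
hsa-miR-1826	1.22729	0.0339	3.11047	0.0832
hsa-miR-18b	0.80097	0.0894	0.86415	0.0261
hsa-miR-320c	1.18737	0.0490	0	0.0368
hsa-mir-565-Pre	1.37948	0.0744	1.02796	0.0482
hsa-mir-566-Pre	0.59372	0.0217	1.29855	0.1471
hsa-mir-595	0	0	0	0
hsa-miR-768-3p	1.16511	0.0261	0	0
hsa-miR-768-5p	1.28797	0.0771	0	0
hsa-miR-886-5p	1.08908	0.0675	0.76209	0.0305
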