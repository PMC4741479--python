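mirna_id	genotype	call	effect	threshold_used
hsa-let-7e	ATM_null	up	0.42886	0.067
hsa-let-7f	ATM_null	up	0.62202	0.0682
hsa-let-7g	ATM_null	unchanged	0.07888000000000006	0.094
hsa-mir-016	ATM_null	up	1.2489599999999998	0.2924
hsa-mir-019a	ATM_null	down	-0.08831999999999995	0.0596
hsa-mir-019b	ATM_null	unchanged	-0.07579999999999998	0.122
hsa-mir-020a	ATM_null	unchanged	-0.17842000000000002	0.3828
hsa-mir-027a	ATM_null	up	0.4020699999999999	0.0712
hsa-mir-029b	ATM_null	up	0.56938	0.355
hsa-mir-029c	ATM_null	unchanged	0.20673000000000008	0.3766
hsa-mir-030c	ATM_null	up	0.60287	0.2514
hsa-mir-030e 3p	ATM_null	undetected	-1.0	0.0
hsa-mir-101	ATM_null	down	-0.26176999999999995	0.1034
hsa-mir-106a	ATM_null	up	0.92872	0.1356
hsa-miR-1248	ATM_null	undetected	-1.0	0.0
hsa-miR-1254	ATM_null	undetected	-1.0	0.0
hsa-miR-1308	ATM_null	unchanged	0.06383000000000005	0.194
hsa-mir-142 3p	ATM_null	unchanged	-0.16664999999999996	0.2372
hsa-mir-150	ATM_null	undetected	-1.0	0.0
hsa-miR-1826	ATM_null	up	2.11047	0.1664
hsa-miR-18b	ATM_null	down	-0.13585000000000003	0.0522
hsa-miR-320c	ATM_null	down	-1.0	0.0736
hsa-mir-565-Pre	ATM_null	unchanged	0.027959999999999985	0.0964
hsa-mir-566-Pre	ATM_null	up	0.2985500000000001	0.2942
hsa-mir-595	ATM_null	undetected	-1.0	0.0
hsa-miR-768-3p	ATM_null	undetected	-1.0	0.0
hsa-miR-768-5p	ATM_null	undetected	-1.0	0.0
hsa-miR-886-5p	ATM_null	down	-0.23790999999999995	0.061
# summary genotype=ATM_null sd_multiplier=2.0 n_up=9 n_down=5 n_altered=14 n_undetected=7 n_unchanged=7
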