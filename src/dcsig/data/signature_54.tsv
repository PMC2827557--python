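gene_id	gene_symbol	direction
100423_f_at	STAT5A	up
100540_at	LTA4H	down
100584_at	ANXA4	up
100588_at	PSME2	up
100779_at	IL12B	up
100981_at	IFIT1	up
101072_at	EIF4EBP2	down
101144_at	IL18R1	down
101995_at	SQSTM1	up
102218_at	IL6	up
102310_at	CCL22	up
102779_at	GADD45B	up
102831_s_at	CD86	up
103035_at	TAP1	up
103040_at	CD83	up
103254_at	TRAFD1	up
103402_at	TM7SF3	down
103486_at	IL1B	up
103494_at	TSPAN8	down
103665_at	ELOVL6	down
104149_at	NFKBIA	up
104376_at	HDAC5	down
104418_at	ZNRF2	down
104443_at	CCR7	up
160501_at	KIF20A	down
160608_at	RAB20	up
161005_at	TXNDC16	down
92962_at	CD40	up
93092_at	H2-DMA	down
93367_at	TEP1	down
93448_at	DAGLB	down
94186_at	TRAF1	up
94256_at	CLIC4	up
94294_at	CCNB2	down
94501_at	SGPP1	down
94752_s_at	SKIL	up
94814_at	GNAI3	up
94881_at	CDKN1A	up
94928_at	TNFRSF1B	up
95024_at	USP18	up
96120_at	DNAJB6	up
96125_at	DAXX	up
96319_at	CDC20	down
96515_at	IL4I1	up
96752_at	ICAM1	up
96935_at	PDZK1IP1	up
98002_at	IRF8	up
98405_at	SERPINB9	up
98427_s_at	NFKB1	up
98500_at	IL1RL1	down
98822_at	ISG15	up
98988_at	NFKBIZ	up
99562_at	MAN2B1	down
99982_at	NFKBIB	up
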