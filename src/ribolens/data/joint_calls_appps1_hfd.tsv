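contrast	gene	rna_call	ribo_call
Nor_vs_AD	Sgk1	up	up
Nor_vs_AD	Myo1f	up	up
Nor_vs_AD	Oip5	up	up
Nor_vs_AD	Cst7	up	up
Nor_vs_AD	Iqschfp	down	down
Nor_vs_AD	Gm45837	down	down
Nor_vs_AD	Itga2b	down	down
Nor_vs_AD	Alb	down	down
Nor_vs_AD	Npas4	down	down
Nor_vs_AD	Fos	down	down
Nor_vs_AD	Ccn1	down	down
Nor_vs_AD	Dusp1	down	down
Nor_vs_AD	Npy	up	down
Nor_vs_AD	Ptchd4	up	down
Nor_vs_AD	Clcc1	up	down
Nor_vs_AD	Thbs4	up	down
Nor_vs_AD	Cdh12	up	down
Nor_vs_AD	Grid2ip	down	up
Nor_vs_AD	Gucy2c	down	up
Nor_vs_AD	Th	down	up
Nor_vs_AD	Eva1a	down	up
Nor_vs_AD	Ngb	down	up
Nor_vs_AD	Slc10a4	down	up
Nor_vs_AD	Hs3st3b1	down	up
Nor_vs_AD	Hspb1	down	up
AD_vs_AD_HFD	Ecm1	up	up
AD_vs_AD_HFD	Reep4	up	up
AD_vs_AD_HFD	Cmtm3	up	up
AD_vs_AD_HFD	Gbp5	down	down
AD_vs_AD_HFD	H1f3	down	down
AD_vs_AD_HFD	H1f4	down	down
AD_vs_AD_HFD	Sspo	up	down
AD_vs_AD_HFD	Hoxb5	up	down
AD_vs_AD_HFD	Ccm2	up	down
AD_vs_AD_HFD	Slc1a1	down	up
AD_vs_AD_HFD	Glt8d2	down	up
AD_vs_AD_HFD	Serinc2	down	up
AD_vs_AD_HFD	Cd34	down	up
AD_vs_AD_HFD	C1ra	down	up
AD_vs_AD_HFD	Thbs4	down	up
AD_vs_AD_HFD	Lct	down	up
AD_vs_AD_HFD	Gm45208	down	up
AD_vs_AD_HFD	Ltf	down	up
AD_vs_AD_HFD	Cnpy1	down	up
AD_HFD_vs_H_H	Alms1	up	up
AD_HFD_vs_H_H	Lcmt2	up	up
AD_HFD_vs_H_H	Ryr3	up	up
AD_HFD_vs_H_H	Ppp1r10	up	up
AD_HFD_vs_H_H	Zfp968	down	down
AD_HFD_vs_H_H	Ccn1	down	down
AD_HFD_vs_H_H	Npas4	down	down
AD_HFD_vs_H_H	Fos	down	down
AD_HFD_vs_H_H	Dusp1	down	down
AD_HFD_vs_H_H	Mpeg1	down	down
AD_HFD_vs_H_H	C1ra	up	down
AD_HFD_vs_H_H	Mpp4	up	down
AD_HFD_vs_H_H	Thbs4	up	down
AD_HFD_vs_H_H	Otof	down	up
AD_HFD_vs_H_H	Abl2	down	up
AD_HFD_vs_H_H	Glra1	down	up
AD_HFD_vs_H_H	Hoxb5	down	up
AD_HFD_vs_H_H	Nrap	down	up
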