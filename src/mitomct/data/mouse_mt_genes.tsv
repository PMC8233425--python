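# Mouse mitochondrial gene coordinates (NC_005089 annotation, 1-based inclusive)
name	start	end	strand	kind
RNR1	70	1024	H	rRNA
RNR2	1094	2675	H	rRNA
ND1	2751	3707	H	protein
ND2	3914	4951	H	protein
COI	5328	6872	H	protein
COII	7013	7696	H	protein
ATP8	7766	7969	H	protein
ATP6	7927	8607	H	protein
COIII	8607	9390	H	protein
ND3	9459	9806	H	protein
ND4L	9877	10173	H	protein
ND4	10167	11544	H	protein
ND5	11742	13565	H	protein
ND6	13552	14070	L	protein
CYTB	14145	15288	H	protein
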