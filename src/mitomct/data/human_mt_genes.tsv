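# Human mitochondrial gene coordinates (rCRS / NC_012920 annotation, 1-based inclusive)
# protein-coding genes plus the two rRNAs; H = heavy strand, L = light strand
name	start	end	strand	kind
RNR1	648	1601	H	rRNA
RNR2	1671	3229	H	rRNA
ND1	3307	4262	H	protein
ND2	4470	5511	H	protein
COI	5904	7445	H	protein
COII	7586	8269	H	protein
ATP8	8366	8572	H	protein
ATP6	8527	9207	H	protein
COIII	9207	9990	H	protein
ND3	10059	10404	H	protein
ND4L	10470	10766	H	protein
ND4	10760	12137	H	protein
ND5	12337	14148	H	protein
ND6	14149	14673	L	protein
CYTB	14747	15887	H	protein
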