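# Human mitochondrial protein-coding ORFs (rCRS chrM, NC_012920.1)
# 0-based coordinates; start = first nucleotide of the start codon,
# stop_first = first nucleotide of the (possibly polyadenylation-completed)
# stop codon, taken as the first base of the last annotated codon.
gene	start	stop_first	strand
ND1	3306	4259	+
ND2	4469	5508	+
COX1	5903	7442	+
COX2	7585	8266	+
ATP8	8365	8569	+
ATP6	8526	9204	+
COX3	9206	9987	+
ND3	10058	10401	+
ND4L	10469	10763	+
ND4	10759	12134	+
ND5	12336	14145	+
ND6	14672	14150	-
CYTB	14746	15884	+
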