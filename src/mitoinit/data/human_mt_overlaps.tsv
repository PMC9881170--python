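# Overlapping ORF regions of the bicistronic human mitochondrial
# transcripts, 0-based half-open genomic intervals on chrM.
gene_a	gene_b	start	end
ATP8	ATP6	8526	8572
ND4L	ND4	10759	10766
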