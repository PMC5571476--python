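label	haplogroup	n_genbank	consequence
T2638C	A2f1	17	synonymous
C2639T	N1b	96	P3S
A2672G	U6a7a1a	16	S14G
G2701A	H13a1a2b	8	synonymous
G2702A	N1a1a	71	A24T
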