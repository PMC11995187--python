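AACGT	MGW	4.0
ACGTA	MGW	4.5
CGTAC	MGW	5.0
GTACG	MGW	5.5
TACGA	MGW	4.0
CCGGA	MGW	4.5
GGCCT	MGW	5.0
TTAAC	MGW	5.5
AATTC	MGW	4.0
CATGC	MGW	4.5
GCATG	MGW	5.0
TGCAA	MGW	5.5
ACCTA	MGW	4.0
CCTAA	MGW	4.5
CTAAT	MGW	5.0
TAATG	MGW	5.5
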