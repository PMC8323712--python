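gene	chrom	start	end
ABCG5	1	1000000	1050000
ABCG8	2	1000000	1050000
ANGPTL3	3	1000000	1050000
ANGPTL4	4	1000000	1050000
ANGPTL8	5	1000000	1050000
APOC3	6	1000000	1050000
APOA5	7	1000000	1050000
APOB	8	1000000	1050000
CETP	9	1000000	1050000
DGAT2	10	1000000	1050000
HMGCR	11	1000000	1050000
LDLR	12	1000000	1050000
LPL	13	1000000	1050000
MTTP	14	1000000	1050000
NPC1L1	15	1000000	1050000
PCSK9	16	1000000	1050000
PPARA	17	1000000	1050000
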