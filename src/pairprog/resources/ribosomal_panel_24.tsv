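gene_symbol	probe_id
RPL9	ILMN_1750507
RPL12	ILMN_2116366
RPL26	ILMN_1731546
RPL37	ILMN_2191634
RPL31	ILMN_1754195
RPL41	ILMN_2331890
RPL30	ILMN_1754303
RPS9	ILMN_1749447
RPS15A	ILMN_1787949
RPS25	ILMN_1746516
RPS11	ILMN_1740587
RPS4X	ILMN_2166831
RPL19	ILMN_1701832
RPL32	ILMN_2400143
RPS5	ILMN_1707810
RPL34	ILMN_1706873
RPL3	ILMN_2319994
RPL36	ILMN_1685088
RPS2	ILMN_2218277
RPL15	ILMN_1762747
RPS13	ILMN_1777344
RPL18A	ILMN_2141452
RPS12	ILMN_1782621
RPL17	ILMN_1655422
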