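compound_id	source	name
NCI1	NCI	
NCI2	NCI	
NCI3	NCI	
NCI4	NCI	
NCI5	NCI	
NCI6	NCI	
NCI7	NCI	
NCI8	NCI	
NCI9	NCI	
NCI10	NCI	
NCI11	NCI	
NCI12	NCI	
NCI13	NCI	
NCI14	NCI	
NCI15	NCI	
NCI16	NCI	
NCI17	NCI	
NCI18	NCI	
NCI19	NCI	
NCI20	NCI	
NCI21	NCI	
NCI22	NCI	
NCI23	NCI	
NCI24	NCI	
NCI25	NCI	
NCI26	NCI	
NCI27	NCI	
NCI28	NCI	
NCI29	NCI	
NCI30	NCI	
NCI31	NCI	
NCI32	NCI	
NCI33	NCI	
NCI34	NCI	
NCI35	NCI	
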