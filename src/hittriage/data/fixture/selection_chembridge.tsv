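compound_id	source	name
CB1	CHEMBRIDGE	
CB2	CHEMBRIDGE	
CB3	CHEMBRIDGE	
CB4	CHEMBRIDGE	
CB5	CHEMBRIDGE	
CB6	CHEMBRIDGE	
CB7	CHEMBRIDGE	
CB8	CHEMBRIDGE	
CB9	CHEMBRIDGE	
CB10	CHEMBRIDGE	
CB11	CHEMBRIDGE	
CB12	CHEMBRIDGE	
CB13	CHEMBRIDGE	
CB14	CHEMBRIDGE	
CB15	CHEMBRIDGE	
CB16	CHEMBRIDGE	
CB17	CHEMBRIDGE	
CB18	CHEMBRIDGE	
CB19	CHEMBRIDGE	
CB20	CHEMBRIDGE	
CB21	CHEMBRIDGE	
CB22	CHEMBRIDGE	
CB23	CHEMBRIDGE	
CB24	CHEMBRIDGE	
CB25	CHEMBRIDGE	
CB26	CHEMBRIDGE	
CB27	CHEMBRIDGE	
CB28	CHEMBRIDGE	
CB29	CHEMBRIDGE	
CB30	CHEMBRIDGE	
CB31	CHEMBRIDGE	
CB32	CHEMBRIDGE	
CB33	CHEMBRIDGE	
CB34	CHEMBRIDGE	
CB35	CHEMBRIDGE	
CB36	CHEMBRIDGE	
CB37	CHEMBRIDGE	
CB38	CHEMBRIDGE	
CB39	CHEMBRIDGE	
CB40	CHEMBRIDGE	
CB41	CHEMBRIDGE	
CB42	CHEMBRIDGE	
CB43	CHEMBRIDGE	
CB44	CHEMBRIDGE	
CB45	CHEMBRIDGE	
CB46	CHEMBRIDGE	
CB47	CHEMBRIDGE	
CB48	CHEMBRIDGE	
CB49	CHEMBRIDGE	
CB50	CHEMBRIDGE	
CB51	CHEMBRIDGE	
CB52	CHEMBRIDGE	
CB53	CHEMBRIDGE	
CB54	CHEMBRIDGE	
CB55	CHEMBRIDGE	
CB56	CHEMBRIDGE	
CB57	CHEMBRIDGE	
CB58	CHEMBRIDGE	
CB59	CHEMBRIDGE	
CB60	CHEMBRIDGE	
CB61	CHEMBRIDGE	
CB62	CHEMBRIDGE	
CB63	CHEMBRIDGE	
CB64	CHEMBRIDGE	
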