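compound_id	source	name
DB1	DRUGBANK	Terfenadine
DB2	DRUGBANK	Travoprost
DB3	DRUGBANK	Bisoprolol
DB4	DRUGBANK	Gadoteridol
DB5	DRUGBANK	Betaxolol
DB6	DRUGBANK	Ibutilide
DB7	DRUGBANK	Reboxetine
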