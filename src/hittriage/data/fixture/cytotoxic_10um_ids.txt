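CB10
CB61
DB1
NCI21
NCI25
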