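CB1
CB18
CB23
CB25
CB27
CB36
CB39
CB40
CB47
CB48
CB50
CB53
CB57
CB60
CB64
DB7
NCI11
NCI12
NCI18
NCI27
NCI31
NCI33
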