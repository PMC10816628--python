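{
 "CHEMBRIDGE": {
  "stage1_discarded": 29,
  "routed_10uM": 9
 },
 "DRUGBANK": {
  "stage1_discarded": 4,
  "routed_10uM": 2
 },
 "NCI": {
  "stage1_discarded": 13,
  "routed_10uM": 12
 }
}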