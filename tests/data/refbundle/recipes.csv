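parent_code,ingredient_code,weight_fraction
11000001,10000003,0.5
11000001,10000004,0.3
11000001,10000007,0.2
11000002,10000001,0.7
11000002,10000009,0.2
11000002,10000007,0.1
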