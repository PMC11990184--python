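food_code,nova_group
10000001,1
10000002,1
10000003,1
10000004,1
10000005,3
10000006,4
10000007,2
10000008,3
10000009,1
10000010,1
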