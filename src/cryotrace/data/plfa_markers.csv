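marker,fungal,gram_positive,bacterial,general,primary_group,unsaturated
15:0,0,0,0,1,general,0
a15:0,0,1,0,0,bacterial,0
i16:0,0,1,0,0,bacterial,0
16:0,0,0,0,1,general,0
16:1ω5,0,0,0,1,general,1
16:1ω7,0,1,1,0,bacterial,1
16:1ω9,0,0,0,1,general,1
10Me16:0,0,1,0,0,bacterial,0
17:0,0,0,0,1,general,0
a17:0,0,1,0,0,bacterial,0
cy17:0,0,1,1,0,bacterial,0
18:1ω9cis,1,0,0,0,fungal,1
18:1ω9trans,0,0,0,1,general,1
"18:2ω6,9",1,0,0,0,fungal,1
10Me18:0,0,1,0,0,bacterial,0
cy19:0,0,0,1,0,bacterial,0
19:1ω9,0,0,0,1,general,1
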