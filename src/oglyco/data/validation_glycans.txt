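# Multiply-reported experimentally determined mucin O-glycans
# (structure identifiers; one per line)
[S3L3]VT
[S6][S3L3]VT
[S3L4Y6][S3L3]VT
[S3L4Y6][L3]VT
[L4Y6][S3L3]VT
[S6][L3]VT
[L4Y6][L3]VT
[L3]VT
[Y6][S3L3]VT
[S6]VT
[L4[f3]Y6][S3L3]VT
[S3L4[f3]Y6][S3L3]VT
[S3L4[f3]Y6][L3]VT
[L4Y3L4Y6][S3L3]VT
VT
[Y6][L3]VT
[S6][Y3]VT
[S6][L4Y3]VT
[L4[f3]Y6][L3]VT
[L4Y3L4Y6][L3]VT
[Y3]VT
[Y3L4Y6][L3]VT
[S6][S6L4Y3]VT
[S6L4Y6][S3L3]VT
[S6L4Y3L4Y6][S3L3]VT
[S3L4[f3]Y6][[S3L4[f3]Y6][S3L4[f3]Y3]L3]VT
[S3L4[f3]Y6][[S3L4[f3]Y6][L4[f3]Y3]L3]VT
[S3L4[f3]Y6][[S3L4Y6][S3L4[f3]Y3]L3]VT
[S3L4[f3]Y6][[L4[f3]Y6][S3L4[f3]Y3]L3]VT
[S3L4[f3]Y6][[L4[f3]Y6][S3L4Y3]L3]VT
[S3L4[f3]Y6][[L4Y6][S3L4[f3]Y3]L3]VT
[S3L4Y6][[S3L4[f3]Y6][S3L4[f3]Y3]L3]VT
[S3L4Y6][[L4[f3]Y6][S3L4[f3]Y3]L3]VT
[S3L4Y3]VT
[S3L4Y3L4Y6][S3L3]VT
[S3L4Y3L3]VT
[L4[s6]Y6][S3L3]VT
[L4[f3]Y6][[S3L4[f3]Y6][S3L4[f3]Y3]L3]VT
[L4[f3]Y3L4Y6][S3L3]VT
[L4Y6][[L4Y6][L4Y3]L3]VT
[L4Y3]VT
[L4Y3L4[f3]Y6][L3]VT
[L4Y3L4Y3]VT
[L4Y3L4Y3L4Y6][L3]VT
[L4Y3L3]VT
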