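month,NSS,NSS_inside_lake,CSS,LV
2,7,0,32,0
3,108,38,440,113
4,32,14,68,86
5,8,5,61,95
6,0,0,66,77
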