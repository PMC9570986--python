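class,1a,1b,2,3or4,5
1a,249,14,0,3,0
1b,1,307,0,2,2
2,0,0,259,1,2
3or4,5,5,12,553,39
5,0,0,0,23,246
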