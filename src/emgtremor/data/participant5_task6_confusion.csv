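class,1a,1b,2,3,4,5
1a,190,39,0,6,31,20
1b,4,308,0,0,0,0
2,0,0,258,0,4,0
3,4,0,23,172,88,21
4,2,5,5,76,216,3
5,0,4,0,20,21,233
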