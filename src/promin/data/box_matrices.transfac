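ID BOX_TATA
NA TATA
P0      A      C      G      T
01      4      4      4     88
02     88      4      4      4
03      4      4      4     88
04     88      4      4      4
05     46      4      4     46
06     88      4      4      4
07     46      4      4     46
//
ID BOX_CCAAT
NA CCAAT
P0      A      C      G      T
01      4     88      4      4
02      4     88      4      4
03     88      4      4      4
04     88      4      4      4
05      4      4      4     88
//
ID BOX_GC
NA GC
P0      A      C      G      T
01      4      4     88      4
02      4      4     88      4
03      4      4     88      4
04      4     88      4      4
05      4      4     88      4
06      4      4     88      4
//
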