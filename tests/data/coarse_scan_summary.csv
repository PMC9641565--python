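scan_index,sample_type,rows,cols,dwell_ms,extracted_regions,extracted_cells
1,A,321,321,100,41,36
2,A,321,321,100,36,31
3,A,149,321,100,17,14
4,B,321,321,100,19,17
5,B,118,321,100,11,8
6,C,163,163,50,18,18
7,C,163,163,25,16,16
8,C,163,163,12.5,17,16
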