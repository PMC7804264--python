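bird_id,sequence_code,A,B,C
Washington,CAB-FF,2,2,3
Wellington,CAB-EF,0,1,1
Caracas,BCA-FF,7,8,7
Rome,ABC-EF,6,3,7
Lisbon,BCA-EF,7,0,1
Quito,ABC-FF,9,8,8
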