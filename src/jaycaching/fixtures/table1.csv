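bird_id,sequence_code,A_P,A_M,B_P,B_M,C_P,C_M
Washington,BCA-MP,4,2,2,2,3,3
Wellington,ABC-MP,0,0,0,0,1,0
Caracas,ABC-PM,8,0,11,0,9,0
Lisbon,CAB-MP,1,0,0,1,0,5
Jerusalem,BCA-PM,2,0,3,0,4,1
Quito,CAB-PM,0,0,0,0,0,0
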