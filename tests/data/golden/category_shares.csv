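basis,category,share
duration,A,0.1257
duration,B,0.2130
duration,C,0.1119
duration,D,0.4144
duration,E,0.0888
duration,unknown,0.0462
frequency,A,0.1082
frequency,B,0.1828
frequency,C,0.1418
frequency,D,0.4291
frequency,E,0.0746
frequency,unknown,0.0634
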