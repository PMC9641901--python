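density_per_litre,proportion_surviving,development_days
2,0.99036403039501408,10
4,0.98956772832740303,10.2
8,0.98790187168275445,10.5
16,0.98392032068131308,11
32,0.97182580167812482,12
64,0.91660493194814729,14
128,0.48615022477528552,17
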