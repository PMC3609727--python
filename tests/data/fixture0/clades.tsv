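name	n_min	n_max_known	tips
cladeA	6		t1;t2;t3;t4;t5;t6
cladeB	6	18	t10;t11;t12;t7;t8;t9
cladeC	3		t1;t2;t3
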