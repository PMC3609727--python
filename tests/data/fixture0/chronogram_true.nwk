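(((((t1:0.3264246330463765,t2:0.3264246330463765):0.044251255274156076,(t3:0.18168687329875954,t4:0.18168687329875954):0.188989015021773):1.3455695821573723,(t5:0.4919520353983238,t6:0.4919520353983238):1.224293435079581):0.5433134782194617,(((t7:0.3223130554035225,t8:0.3223130554035225):0.5478214240392858,(t9:0.21929324473827805,t10:0.21929324473827805):0.6508412347045303):0.6572856515787486,t11:1.527420131021557):0.7321388176758097):0.009903331294527806,t12:2.2694622799918944);
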