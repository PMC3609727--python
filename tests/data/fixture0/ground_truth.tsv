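node_id	age_myr	branch_rate
t1	0.0	0.007013572734008254
t2	0.0	0.009046754788977953
n2	0.3264246330463765	0.0074655053474331
t3	0.0	0.00856073515077221
t4	0.0	0.006552697400172858
n5	0.18168687329875954	0.0086056329653744
n6	0.37067588832053255	0.008315167954346822
t5	0.0	0.01092481479138061
t6	0.0	0.00869604132914892
n9	0.4919520353983238	0.010958204579708728
n10	1.7162454704779049	0.009068701992360068
t7	0.0	0.011495360547635048
t8	0.0	0.010088367297724565
n13	0.3223130554035225	0.01151753263503832
t9	0.0	0.009982457663033014
t10	0.0	0.009011065236355555
n16	0.21929324473827805	0.010426717268992991
n17	0.8701344794428083	0.010244419097615618
t11	0.0	0.010335162290476133
n19	1.527420131021557	0.010076663413519371
n20	2.2595589486973666	0.01005310820677366
t12	0.0	0.0114153923872204
n22	2.2694622799918944	
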