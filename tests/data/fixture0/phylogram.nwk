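(((((t1:0.002289402906042716,t2:0.0029530836122526774):0.00033035798287983935,(t3:0.0015553732026825878,t4:0.0011905391023103171):0.0016263700977650075):0.011188637069898826,(t5:0.005374484872969405,t6:0.004278035231782756):0.013416057927196396):0.0049271480224049105,(((t7:0.003705104781073362,t8:0.003251612487762582):0.00630955112954564,(t9:0.002189085531388998,t10:0.001976065734228708):0.006786137541266446):0.006733509681622058,t11:0.01578613493984811):0.007377516437691161):9.955926111141591e-05,t12:0.025906802434103322);
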