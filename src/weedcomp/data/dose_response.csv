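biotype,herbicide,hrac_group,rating,ed50_g_ha
R,fenoxaprop-P,A,RRR,>2650
R,pinoxaden,A,RRR,684
R,piroxulam,B,RRR,>288
R,iodosulfuron,B,RRR,>3200
R,pendimethalin,K1,RRR,>51000
S,fenoxaprop-P,A,S,<51.0
S,pinoxaden,A,S,<25.5
S,piroxulam,B,S,<12.5
S,iodosulfuron,B,S,<5.0
S,pendimethalin,K1,S,<300
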