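strain,titre_g_l,glucose_g_l,od600,note
QLW1,0.136,20,,MCR split + ACC1 overexpression
QLW2,0.39,20,,+ phosphoketolase pathway
QLW3,0.65,20,,+ Acc1 S659A S1157A
QLW5,0.74,20,6.97,+ STB5 via ARTp (control for transporter tests)
QLW6,0.70,20,,+ NCE103 carbonic anhydrase
QLW8,0.83,20,7.65,+ SUL1 bicarbonate importer
QLW10,0.31,20,,STB5 + SUL1 combined (OAA overflow)
QLW12,0.44,20,,+ CIT1 overexpression
QLW13,0.45,20,,+ Cit1 S462A
QLW15,1.18,20,,+ PTC7 overexpression
QLW19,1.34,20,,+ YHM2 + IDP2
QLW23,4.12,20,,MCR domain copy-number tuning
QLW71,11.25,20,,final strain
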