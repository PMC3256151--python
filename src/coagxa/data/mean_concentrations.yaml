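# Mean plasma concentrations (mol/L) corresponding to a 100% factor level.
# Literature values for the average healthy adult; a subject's percent-of-mean
# level is multiplied by these to obtain the molar input of the simulation.
fII:   1.4e-6    # prothrombin, 1.4 uM
fV:    2.0e-8    # 20 nM
fVII:  1.0e-8    # 10 nM (circulating fVIIa is derived as 1% of fVII)
fVIII: 7.0e-10   # 0.7 nM
fIX:   9.0e-8    # 90 nM
fX:    1.7e-7    # ~170 nM
AT:    3.4e-6    # antithrombin, 3.4 uM
TFPI:  2.5e-9    # 2.5 nM
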