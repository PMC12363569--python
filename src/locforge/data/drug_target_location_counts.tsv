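# Drug-target subcellular localization audit: per-location counts of
# true targets, predicted targets, and correct predictions (hits) for
# 1,994 validated drug targets across 9 major compartments.
location	true	predicted	hit
Cell membrane	751	674	611
Cytoplasm	859	695	598
Endoplasmic reticulum	163	90	79
Extracellular	236	194	165
Golgi apparatus	105	14	11
Lysosome/Vacuole	63	45	26
Mitochondrion	190	111	107
Nucleus	706	506	464
Peroxisome	11	6	4
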