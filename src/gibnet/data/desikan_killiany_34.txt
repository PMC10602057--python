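bankssts
caudalanteriorcingulate
caudalmiddlefrontal
cuneus
entorhinal
frontalpole
fusiform
inferiorparietal
inferiortemporal
insula
isthmuscingulate
lateraloccipital
lateralorbitofrontal
lingual
medialorbitofrontal
middletemporal
paracentral
parahippocampal
parsopercularis
parsorbitalis
parstriangularis
pericalcarine
postcentral
posteriorcingulate
precentral
precuneus
rostralanteriorcingulate
rostralmiddlefrontal
superiorfrontal
superiorparietal
superiortemporal
supramarginal
temporalpole
transversetemporal
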