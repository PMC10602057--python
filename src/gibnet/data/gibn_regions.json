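{
  "SA1": ["inferiortemporal", "isthmuscingulate", "postcentral", "precuneus", "superiorparietal", "supramarginal", "temporalpole"],
  "SA2": ["caudalanteriorcingulate", "caudalmiddlefrontal", "medialorbitofrontal", "paracentral", "rostralanteriorcingulate"],
  "SA3": ["bankssts", "inferiorparietal", "middletemporal"],
  "SA4": ["parsopercularis", "parsorbitalis", "parstriangularis"],
  "SA5": ["cuneus", "lateraloccipital", "lingual", "pericalcarine"],
  "SA6": ["superiortemporal", "transversetemporal"],
  "CT1": ["bankssts", "caudalmiddlefrontal", "inferiorparietal", "paracentral", "parsopercularis", "postcentral", "precentral", "precuneus", "rostralmiddlefrontal", "superiorfrontal", "superiorparietal", "supramarginal"],
  "CT2": ["caudalanteriorcingulate", "frontalpole", "insula", "lateralorbitofrontal", "medialorbitofrontal", "parsorbitalis", "rostralanteriorcingulate", "rostralmiddlefrontal"],
  "CT3": ["bankssts", "superiortemporal", "temporalpole"],
  "CT4": ["cuneus", "lateraloccipital", "parahippocampal", "pericalcarine"]
}
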