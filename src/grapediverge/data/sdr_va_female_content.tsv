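gene_id	label
Vitis02G0494	PPR-containing protein
Vitis02G0495	YABBY transcription factor
Vitis02G0496	SKU5
Vitis02G0497	beta-fructofuranosidase
Vitis02G0498	aldolase-TPP fusion protein
Vitis02G0499	inaperturate pollen1 INP1
Vitis02G0500	uncharacterized protein
Vitis02G0501	exostosin family protein
Vitis02G0502	KASIII
Vitis02G0503	PLATZ transcription factor
Vitis02G0504	flavin-containing monooxygenase
Vitis02G0505	flavin-containing monooxygenase
Vitis02G0506	flavin-containing monooxygenase
Vitis02G0507	FSEX hypothetical protein
Vitis02G0508	APT3 adenine phosphoribosyltransferase
Vitis02G0509	WRKY transcription factor
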