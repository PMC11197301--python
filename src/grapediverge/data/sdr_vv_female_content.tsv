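gene_id	label
VvCSF_01	PPR-containing protein
VvCSF_02	YABBY transcription factor
VvCSF_03	SKU5
VvCSF_04	beta-fructofuranosidase
VvCSF_05	aldolase-TPP fusion protein
VvCSF_06	inaperturate pollen1 INP1
VvCSF_07	exostosin family protein
VvCSF_08	KASIII
VvCSF_09	PLATZ transcription factor
VvCSF_10	flavin-containing monooxygenase
VvCSF_11	flavin-containing monooxygenase
VvCSF_12	flavin-containing monooxygenase
VvCSF_13	flavin-containing monooxygenase
VvCSF_14	FSEX hypothetical protein
VvCSF_15	APT3 adenine phosphoribosyltransferase
VvCSF_16	WRKY transcription factor
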