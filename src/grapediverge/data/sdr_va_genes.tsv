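gene_id	chrom	start	end	strand	label
Vitis02G0494	chr2	5055465	5058464	+	PPR-containing protein
Vitis02G0495	chr2	5064425	5067424	+	YABBY transcription factor
Vitis02G0496	chr2	5073385	5076384	+	SKU5
Vitis02G0497	chr2	5082345	5085344	+	beta-fructofuranosidase
Vitis02G0498	chr2	5091305	5094304	+	aldolase-TPP fusion protein
Vitis02G0499	chr2	5100265	5103264	+	inaperturate pollen1 INP1
Vitis02G0500	chr2	5109225	5112224	+	uncharacterized protein
Vitis02G0501	chr2	5118185	5121184	+	exostosin family protein
Vitis02G0502	chr2	5127145	5130144	+	KASIII
Vitis02G0503	chr2	5136105	5139104	+	PLATZ transcription factor
Vitis02G0504	chr2	5145065	5148064	+	flavin-containing monooxygenase
Vitis02G0505	chr2	5154025	5157024	+	flavin-containing monooxygenase
Vitis02G0506	chr2	5162985	5165984	+	flavin-containing monooxygenase
Vitis02G0507	chr2	5171945	5174944	+	FSEX hypothetical protein
Vitis02G0508	chr2	5180905	5183904	+	APT3 adenine phosphoribosyltransferase
Vitis02G0509	chr2	5189865	5198824	+	WRKY transcription factor
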