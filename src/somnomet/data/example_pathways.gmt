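purine_metabolism	synthetic example set	hypoxanthine	xanthine	urate	allantoin	urea	inosine	adenosine	adenine	guanine	guanosine
glutathione_metabolism	synthetic example set	gsh	gssg	cysteine	glutamate	glycine	cystathionine
branched_chain_amino_acids	synthetic example set	leucine	isoleucine	valine	ketoleucine	ketoisovalerate
aromatic_amino_acids	synthetic example set	phenylalanine	tyrosine	tryptophan	kynurenine	serotonin
trna_charging	synthetic example set	alanine	arginine	asparagine	aspartate	histidine	lysine	methionine	proline	serine	threonine
energy_metabolism	synthetic example set	atp	adp	amp	creatine	phosphocreatine	lactate	pyruvate	citrate
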