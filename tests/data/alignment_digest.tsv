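read_id	target_id	domain	alignment_score
r01	euk_c1	eukaryote	60
r01	prok_c1	prokaryote	40
r02	prok_c2	prokaryote	55
r02	vir_c1	virus	20
r03	vir_c2	virus	70
r04	euk_c2	eukaryote	50
r04	euk_c3	eukaryote	50
r04	prok_c3	prokaryote	30
r05	euk_c4	eukaryote	60
r05	prok_c4	prokaryote	60
r06	prok_c5	prokaryote	45
r06	vir_c3	virus	45
r07	euk_c5	eukaryote	33
r07	prok_c6	prokaryote	33
r07	vir_c4	virus	33
r08	prok_c7	prokaryote	80
r08	prok_c8	prokaryote	60
r09	euk_c6	eukaryote	90
r09	vir_c5	virus	10
r10	vir_c6	virus	65
r10	prok_c9	prokaryote	64
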