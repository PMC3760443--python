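# Observed [M+H]+ masses, n-nonanoic acid (C9)-enriched feed group.
sample_id	group_label	mz	expected_form	note
c9-01	s (30-31)	2159.02	19-(C9:0)+1	adduct
c9-02	s (30-31)	2001.95	18-(C9:0)
c9-03	t (35-37)	2144.02	19-(C8:0)
c9-04	t (35-37)	2168.02	19-(C10:2)
c9-05	t (35-37)	2286.09	21-(C9:0)	yield_3
c9-06	u (38-41)	2158.03	19-(C9:0)	yield_1
c9-07	v (45-46)	2172.04	19-(C10:0)	yield_2
c9-08	w (49-50)	2228.07	20-(C9:0)-amide	yield_2
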