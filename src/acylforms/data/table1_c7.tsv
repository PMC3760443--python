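# Observed [M+H]+ masses, n-heptanoic acid (C7)-enriched feed group.
# label_anomaly: a 21-residue amide contradicts the glycine-donor rule and
# the same mass is labeled 20-(C10:0)-amide elsewhere; excluded from checks.
sample_id	group_label	mz	expected_form	note
c7-01	h (35-37)	2144.02	19-(C8:0)
c7-02	h (35-37)	2188.05	19-(C10:1)+17	adduct
c7-03	i (38-40)	2170.03	19-(C10:1)	yield_3
c7-04	i (38-40)	2298.07	21-(C10:1)
c7-05	j (42-45)	2300.08	21-(C10:0)	yield_2
c7-06	k (45-47)	2172.04	19-(C10:0)	yield_1
c7-07	l (48-50)	2240.09	20-(C10:1)-amide
c7-08	m (55-56)	2242.09	21-(C10:0)-amide	label_anomaly
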