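# Observed [M+H]+ masses of ghrelin peptides purified from stomach extracts,
# normal-feed (control) group, with the published expected-form labels.
# note values: adduct = printed label carries an adduct shift (+24/+17/+1);
# printed_twice = the published table repeats this row verbatim (kept once);
# yield_1/2/3 = highest / second / third yield marks.
sample_id	group_label	mz	expected_form	note
cont-01	c (33-37)	2144.12	19-(C8:0)	yield_3
cont-02	c (33-37)	2272.17	21-(C8:0)
cont-03	c (33-37)	2168.03	19-(C8:0)+24	adduct
cont-04	c (33-37)	2296.07	21-(C8:0)+24	adduct
cont-05	d (38-40)	2158.04	19-(C9:0)
cont-06	d (38-40)	2170.04	19-(C10:1)	printed_twice
cont-07	d (38-40)	2286.09	21-(C9:0)
cont-08	d (38-40)	2298.09	21-(C10:1)	printed_twice
cont-09	e (43-46)	2214.19	20-(C8:0)-amide
cont-10	e (43-46)	2238.10	20-(C10:2)-amide
cont-11	e (43-46)	2172.06	19-(C10:0)	yield_1
cont-12	f (49-50)	2228.09	20-(C9:0)-amide
cont-13	f (49-50)	2240.09	20-(C10:1)-amide
cont-14	f (49-50)	2240.10	20-(C10:1)-amide
cont-15	g (55-56)	2242.12	20-(C10:0)-amide	yield_2
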