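# Observed [M+H]+ masses, n-octanoic acid (C8)-enriched feed group.
# mass_anomaly: 2146.02 deviates ~+1.8 Da from the 19-(C8:0) theoretical
# value while every sibling entry deviates <=0.23 Da; probable misprint,
# excluded from checks (not corrected).
sample_id	group_label	mz	expected_form	note
c8-01	o (33-37)	2146.02	19-(C8:0)	mass_anomaly
c8-02	o (33-37)	2272.06	21-(C8:0)
c8-03	p (39-41)	2157.98	19-(C9:0)
c8-04	p (39-41)	2170.03	19-(C10:1)	printed_twice
c8-05	q (43-46)	2242.09	20-(C10:0)-amide	yield_3
c8-06	r (55-56)	2214.07	20-(C8:0)-amide	yield_2
c8-07	r (55-56)	2172.03	19-(C10:0)	yield_2
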