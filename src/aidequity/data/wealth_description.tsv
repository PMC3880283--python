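variable	poorest	less_poor	middle	wealthier	wealthiest
n_households	191583	191489	191657	191417	191528
radio_pct	28.7	56.5	61.5	67.2	80.7
electricity_pct	0.9	15.4	63.5	96.9	99.8
flush_toilets_pct	0.4	3.9	26.4	63.9	90.1
refrigerator_pct	0.0	0.2	3.9	45.7	96.5
car_pct	0.0	0.3	1.7	4.3	29.8
rooms_per_person_mean	0.45	0.52	0.55	0.60	0.79
rooms_per_person_sd	0.24	0.41	0.46	0.46	0.63
urban_pct	6.4	16.9	43.6	64.1	81.1
rate_1993_2000	36.9	34.3	23.2	13.6	7.9
exposure_1993_2000	411.6	382.1	310.5	266.1	230.1
rate_2005_2012	23.0	23.2	18.9	12.0	7.1
exposure_2005_2012	492.4	405.1	309.4	264.1	198.4
absolute_decline	13.9	11.1	4.3	1.6	0.8
pct_decline	37.7	32.4	18.5	11.8	10.1
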