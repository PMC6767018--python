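# Ac-225 decay chain bundled nuclide table.
# Columns (tab-separated):
#   name	half_life	half_life_unit	decays_to	gammas	principal_kev	abundance_y
# decays_to: comma list of child:branching_fraction ("-" for a stable sink).
# gammas: semicolon list of energy_keV:intensity (photons per decay), "-" if none
#   is modeled.  The three gamma emitters carry a compact line list: the
#   principal lines sit at the composite-peak energies used for quantification
#   (99.8, 218.1, 440.5 keV) with per-alpha-decay abundances Y = 0.010, 0.114,
#   0.259; secondary lines are approximate evaluated-data values.  Replaceable
#   by a user-supplied table of the same layout.
# Half-lives are the rounded working values (10 d, 4.9 min, 46 min for the
# gamma emitters); at-217 and the sub-bi-213 branch exist for kinetics only.
name	half_life	half_life_unit	decays_to	gammas	principal_kev	abundance_y
Ac-225	10	d	Fr-221:1.0	99.8:0.0100;108.4:0.0024;111.6:0.0027;150.1:0.0062;187.9:0.0054	99.8	0.010
Fr-221	4.9	min	At-217:1.0	218.1:0.1140;99.6:0.0009;409.8:0.0013	218.1	0.114
At-217	32.3	ms	Bi-213:1.0	-	-	-
Bi-213	46	min	Po-213:0.978,Tl-209:0.022	440.5:0.2590;292.8:0.0042	440.5	0.259
Po-213	4.2	us	Pb-209:1.0	-	-	-
Tl-209	2.16	min	Pb-209:1.0	-	-	-
Pb-209	3.23	h	Bi-209:1.0	-	-	-
Bi-209	stable	-	-	-	-	-
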