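gene	protein_change	dataset	region	provean	sift	polyphen2	snps_go	imutant	fathmm	hbond_changed	clash_changed	asa_shift	printed_total
ROBO1	R119Q	lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	false	inter_orbit	8
ROBO1	K103N	lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	false	inter_orbit	8
SLIT2	D435V	lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	9
SLIT2	R306L	lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	9
SLIT2	Y323H	lung	within_docking_domain	Deleterious	Tolerated	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	8
ROBO4	G102C	lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Neutral	Decrease_stability	Passenger	true	true	inter_orbit	8
ROBO4	C207S	lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Cancer_associated	true	false	none	8
ROBO1	R635S	lung	outside_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	9
ROBO1	D312V	lung	outside_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	9
ROBO1	R306I	lung	outside_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	9
SLIT2	P54R	lung	outside_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	9
SLIT2	P665S	lung	outside_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	none	8
ROBO4	G829W	lung	outside_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	9
ROBO4	W367C	lung	outside_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Cancer_associated	true	false	inter_orbit	9
ROBO1	I78S	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	false	inter_orbit	8
ROBO1	G82V	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	false	inter_orbit	8
ROBO1	P123L	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	none	8
ROBO1	R131C	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	false	inter_orbit	8
ROBO1	G143R	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	false	inter_orbit	8
ROBO1	G154E	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	false	inter_orbit	8
SLIT2	C436F	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	9
SLIT2	R388W	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	9
SLIT2	R456H	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	9
SLIT2	N430K	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	9
SLIT2	R420W	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	false	true	inter_orbit	8
SLIT2	L350V	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	false	true	inter_orbit	8
SLIT2	P431L	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	9
SLIT2	L331P	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	none	8
SLIT2	L398F	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	none	8
SLIT2	L371P	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Increase_stability	Passenger	true	true	inter_orbit	8
SLIT2	S352L	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	9
SLIT2	R462C	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	9
SLIT2	A340T	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Neutral	Decrease_stability	Passenger	true	true	inter_orbit	8
SLIT2	P322L	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Neutral	Decrease_stability	Passenger	true	true	inter_orbit	8
SLIT2	R461C	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	false	inter_orbit	8
ROBO4	G86E	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Increase_stability	Passenger	true	true	inter_orbit	8
ROBO4	C207F	non_lung	within_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Cancer_associated	false	true	inter_orbit	9
ROBO1	P176L	non_lung	outside_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	inter_orbit	9
ROBO1	G337V	non_lung	outside_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	none	8
ROBO1	C476Y	non_lung	outside_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	none	8
SLIT2	C215Y	non_lung	outside_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Increase_stability	Cancer_associated	true	true	none	8
SLIT2	G576R	non_lung	outside_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	none	8
SLIT2	S636C	non_lung	outside_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	false	inter_orbit	8
ROBO4	G425V	non_lung	outside_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	none	8
ROBO4	G876V	non_lung	outside_docking_domain	Deleterious	Damaging	Probably_damaging	Disease	Decrease_stability	Passenger	true	true	none	8
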