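# Reference whole-body compartment table for a 60-kg, 1.7-m adult male.
# Columns: name, blood_flow (ml/min), v_iv (ml, intravascular), v_ec (ml,
# extracellular), n_sub (sub-compartments in series), k_tc (1/min,
# transcapillary exchange coefficient; 0 for pure vessels/chambers).
# Flows follow resting regional-circulation fractions normalised to a
# left-heart output of exactly 6500 ml/min.  The injection path
# (peripheral vein -> superior vena cava -> right heart) carries small
# conduit volumes; the large systemic venous reservoir drains the organ
# returns, so it does not delay the injected bolus.
name	blood_flow	v_iv	v_ec	n_sub	k_tc
right_heart	6500	180	0	15	0
lungs	6500	500	150	15	0.1
left_heart	6500	180	0	15	0
ascending_aorta	6500	100	0	15	0
abdominal_aorta	4940	80	0	15	0
myocardium	260	100	80	15	0.2
head	780	300	250	15	0.02
upper_extremities	520	250	400	15	0.15
peripheral_vein	520	30	0	15	0
superior_vena_cava	1300	40	0	15	0
stomach	65	35	50	15	0.3
spleen	195	150	60	15	0.4
pancreas	65	30	40	15	0.3
intestines	877.5	300	400	15	0.3
liver	1625	450	400	15	0.5
kidneys	1235	150	120	15	0.4
lower_body	2080	650	1500	15	0.15
venous_pool	5200	1300	0	15	0
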