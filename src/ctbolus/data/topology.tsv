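# Directed blood-flow edges of the reference circulation (ml/min at 6500
# ml/min left-heart output).  Portal drainage of stomach/spleen/pancreas/
# intestines passes through the liver; the antecubital injection site is
# the peripheral_vein compartment downstream of the upper extremities.
source	destination	flow
right_heart	lungs	6500
lungs	left_heart	6500
left_heart	ascending_aorta	6500
ascending_aorta	myocardium	260
ascending_aorta	head	780
ascending_aorta	upper_extremities	520
ascending_aorta	abdominal_aorta	4940
abdominal_aorta	stomach	65
abdominal_aorta	spleen	195
abdominal_aorta	pancreas	65
abdominal_aorta	intestines	877.5
abdominal_aorta	liver	422.5
abdominal_aorta	kidneys	1235
abdominal_aorta	lower_body	2080
stomach	liver	65
spleen	liver	195
pancreas	liver	65
intestines	liver	877.5
liver	venous_pool	1625
kidneys	venous_pool	1235
lower_body	venous_pool	2080
myocardium	venous_pool	260
head	superior_vena_cava	780
upper_extremities	peripheral_vein	520
peripheral_vein	superior_vena_cava	520
superior_vena_cava	right_heart	1300
venous_pool	right_heart	5200
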