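node	degree	core
chest pain	2	2
chest distress	4	3
short breath	7	3
cardiopalmus	3	3
cough	7	2
hypodynamia	5	3
spontaneous perspiration	4	3
night sweat	2	1
burning sensation of five centres	1	1
eyestrain	2	1
dry mouth	1	1
dizziness	3	3
amnesia	10	3
fainting feeling	4	3
tinnitus	6	3
insomnia	2	2
irritable tantrum	8	3
hypochondrium distending pain	3	3
sighing	4	3
depression	2	2
anorexia	7	3
abdominal distension	5	3
epigastric fullness	2	2
belching	2	2
nausea and vomiting	4	3
sore waist and knee	9	3
frequency of micturition at night	2	2
limb numbness	3	3
heel pain	1	1
pachylosis	1	1
obesity	2	2
white phlegm	8	3
yellow phlegm	1	1
frothy phlegm	1	1
tastelessness in the mouth	7	3
bitter taste in the mouth	3	2
sweet taste in the mouth	3	2
salty taste in the mouth	3	2
viscous and greasy taste in the mouth	1	1
yellow urine and oliguria	1	1
clear urine in large amounts	2	1
residual urine	2	2
cold abdomen and waist	1	1
heavy limbs	8	3
darkish complexion	2	2
red complexion	1	1
conjunctival congestion	1	1
dark color around eyes	5	3
dark red lip gingiva	3	3
pale lips and finger nails	2	2
dark color in palatal mucosa	2	1
lower abdominal tenderness	2	1
faint low voice	9	3
emaciation	1	1
swollen tongue body	7	3
tooth-marked tongue	6	3
thick tongue coating	1	1
greasy tongue coating	1	1
thick and greasy tongue coating	3	3
yellow tongue coating	6	3
glossal petechia	3	3
lavender subglossal collateral vessels	2	2
blue purple subglossal collateral vessels	3	3
mauve subglossal collateral vessels	1	1
subglossal collateral vessels engorgement	11	3
deep pulse	1	1
thready pulse	1	1
uneven pulse	2	2
weak pulse	5	3
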