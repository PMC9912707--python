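# version: seed-v1
term,type,categories,is_medication,is_clinician_authored,is_symptom_specific,source,rationale
pain,keyword,pain,false,false,true,development-corpus,
painful,keyword,pain,false,false,true,development-corpus,
painkiller,keyword,pain,true,false,false,validation-adjustment,
ache,keyword,pain,false,false,true,development-corpus,
aching,keyword,pain,false,false,true,development-corpus,
hurts,keyword,pain,false,false,true,development-corpus,
hurting,keyword,pain,false,false,true,development-corpus,
sore,keyword,pain,false,false,true,development-corpus,
morphine,keyword,pain,true,false,false,a-priori,
oxycodone,keyword,pain,true,false,false,a-priori,
nausea,keyword,GI,false,false,true,development-corpus,
nauseous,keyword,GI,false,false,true,development-corpus,
vomiting,keyword,GI,false,false,true,development-corpus,
throwing up,keyword,GI,false,false,true,development-corpus,
diarrhea,keyword,GI,false,false,true,development-corpus,
constipation,keyword,GI,false,false,true,development-corpus,
constipated,keyword,GI,false,false,true,development-corpus,
bowels,keyword,GI,false,true,true,development-corpus,
appetite,keyword,GI,false,false,true,development-corpus,
stool softener,keyword,GI,true,false,false,development-corpus,
stool softeners,keyword,GI,true,false,false,development-corpus,
heartburn,keyword,GI,false,false,true,development-corpus,
zofran,keyword,GI,true,false,false,a-priori,
insomnia,keyword,sleep/wake,false,true,true,development-corpus,
sleepy,keyword,sleep/wake,false,false,true,development-corpus,
drowsy,keyword,sleep/wake,false,false,true,development-corpus,
fatigue,keyword,sleep/wake,false,true,true,development-corpus,
fatigued,keyword,sleep/wake,false,false,true,development-corpus,
exhausted,keyword,sleep/wake,false,false,true,development-corpus,
ambien,keyword,sleep/wake,true,false,false,a-priori,
numbness,keyword,neurological,false,false,true,development-corpus,
tingling,keyword,neurological,false,false,true,development-corpus,
neuropathy,keyword,neurological,false,true,true,development-corpus,
dizzy,keyword,neurological,false,false,true,development-corpus,
dizziness,keyword,neurological,false,false,true,development-corpus,
headache,keyword,neurological;pain,false,false,true,development-corpus,
headaches,keyword,neurological;pain,false,false,true,development-corpus,
fuzzy brain,keyword,neurological,false,false,true,validation-adjustment,
rash,keyword,cutaneous,false,false,true,development-corpus,
itching,keyword,cutaneous,false,false,true,development-corpus,
itchy,keyword,cutaneous,false,false,true,development-corpus,
dry skin,keyword,cutaneous,false,false,true,development-corpus,
swelling,keyword,cutaneous;other,false,false,true,development-corpus,
anxiety,keyword,mood/anxiety,false,true,true,development-corpus,
anxious,keyword,mood/anxiety,false,false,true,development-corpus,
worried,keyword,mood/anxiety,false,false,false,development-corpus,
worry,keyword,mood/anxiety,false,false,false,development-corpus,
depressed,keyword,mood/anxiety,false,false,true,development-corpus,
depression,keyword,mood/anxiety,false,true,true,development-corpus,
stressed,keyword,mood/anxiety,false,false,false,development-corpus,
ativan,keyword,mood/anxiety,true,false,false,a-priori,
lorazepam,keyword,mood/anxiety,true,false,false,a-priori,
breathless,keyword,respiratory,false,false,true,validation-adjustment,
short of breath,keyword,respiratory,false,false,true,development-corpus,
shortness of breath,keyword,respiratory,false,true,true,development-corpus,
wheezing,keyword,respiratory,false,false,true,development-corpus,
cough,keyword,respiratory,false,false,true,development-corpus,
coughing,keyword,respiratory,false,false,true,development-corpus,
mouth sores,keyword,oral,false,false,true,development-corpus,
dry mouth,keyword,oral,false,false,true,development-corpus,
libido,keyword,sexual,false,true,true,a-priori,
hot flashes,keyword,other,false,false,true,development-corpus,
chills,keyword,other,false,false,true,development-corpus,
fever,keyword,other,false,true,true,development-corpus,
deep breath,exclusion,,,,,,physical-exam instruction; not a symptom description
deep breaths,exclusion,,,,,,physical-exam instruction; not a symptom description
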