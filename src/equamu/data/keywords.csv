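term,category
anämie,Blood/Hematopoietic organs
blutarmut,Blood/Hematopoietic organs
thrombozytopenie,Blood/Hematopoietic organs
gerinnungsstörung,Blood/Hematopoietic organs
piroplasmose,Blood/Hematopoietic organs
hämolyse,Blood/Hematopoietic organs
petechien,Blood/Hematopoietic organs
abszess,Dermatology
phlegmone,Dermatology
dermatitis,Dermatology
mauke,Dermatology
ekzem,Dermatology
sommerekzem,Dermatology
urtikaria,Dermatology
hautpilz,Dermatology
räude,Dermatology
juckreiz,Dermatology
impfung,Diagnostics/Therapy
kastration,Diagnostics/Therapy
euthanasie,Diagnostics/Therapy
röntgen,Diagnostics/Therapy
blutentnahme,Diagnostics/Therapy
zahnbehandlung,Diagnostics/Therapy
endoskopie,Diagnostics/Therapy
biopsie,Diagnostics/Therapy
tupferprobe,Diagnostics/Therapy
cushing,Endocrinology
ppid,Endocrinology
schilddrüse,Endocrinology
insulinresistenz,Endocrinology
hormonstörung,Endocrinology
stoffwechselstörung,Endocrinology
allergie,Immune system
anaphylaxie,Immune system
autoimmunerkrankung,Immune system
immunschwäche,Immune system
hyposensibilisierung,Immune system
impfreaktion,Immune system
vergiftung,Intoxication
intoxikation,Intoxication
botulismus,Intoxication
schwermetallvergiftung,Intoxication
giftpflanzen,Intoxication
jakobskreuzkraut,Intoxication
herzgeräusch,Cardiology
arrhythmie,Cardiology
herzinsuffizienz,Cardiology
endokarditis,Cardiology
myokarditis,Cardiology
vorhofflimmern,Cardiology
perikarderguss,Cardiology
ataxie,Neurology
headshaking,Neurology
fazialislähmung,Neurology
epilepsie,Neurology
tetanus,Neurology
nervenlähmung,Neurology
wobbler,Neurology
notfall,Emergency
notdienst,Emergency
festliegen,Emergency
kreislaufkollaps,Emergency
akutversorgung,Emergency
sarkoid,Oncology
melanom,Oncology
tumor,Oncology
karzinom,Oncology
lymphom,Oncology
neoplasie,Oncology
fibrosarkom,Oncology
konjunktivitis,Ophthalmology
hornhautulkus,Ophthalmology
keratitis,Ophthalmology
uveitis,Ophthalmology
augenausfluss,Ophthalmology
periodische augenentzündung,Ophthalmology
tränenkanal,Ophthalmology
mondblindheit,Ophthalmology
lahmheit,Orthopedics
arthritis,Orthopedics
arthrose,Orthopedics
hufrehe,Orthopedics
sehnenschaden,Orthopedics
spat,Orthopedics
hufabszess,Orthopedics
gelenkentzündung,Orthopedics
fesselträgerschaden,Orthopedics
ohrenentzündung,Otology
otitis,Otology
ohrenausfluss,Otology
ohrmilben,Otology
ohrhämatom,Otology
husten,Respiratory system
bronchitis,Respiratory system
influenza,Respiratory system
druse,Respiratory system
nasenausfluss,Respiratory system
dämpfigkeit,Respiratory system
equines asthma,Respiratory system
lungenentzündung,Respiratory system
kehlkopfpfeifen,Respiratory system
entwurmung,Routine exam/prevention
wurmkur,Routine exam/prevention
mikrochip,Routine exam/prevention
ankaufsuntersuchung,Routine exam/prevention
routineuntersuchung,Routine exam/prevention
prophylaxe,Routine exam/prevention
zahnkontrolle,Routine exam/prevention
medikamentenabgabe,Routine exam/prevention
fieber,Systemic disease
lethargie,Systemic disease
inappetenz,Systemic disease
abgeschlagenheit,Systemic disease
allgemeininfektion,Systemic disease
septikämie,Systemic disease
anorexie,Systemic disease
wunde,Trauma
verletzung,Trauma
fraktur,Trauma
prellung,Trauma
bissverletzung,Trauma
schnittwunde,Trauma
platzwunde,Trauma
hämatom,Trauma
ultraschall,Unclear/unspecified
ödem,Unclear/unspecified
schwellung,Unclear/unspecified
umfangsvermehrung,Unclear/unspecified
befund,Unclear/unspecified
zystitis,Urogenital system
blasenentzündung,Urogenital system
nierenerkrankung,Urogenital system
endometritis,Urogenital system
gebärmutterentzündung,Urogenital system
harnwegsinfekt,Urogenital system
trächtigkeitsuntersuchung,Urogenital system
hodenentzündung,Urogenital system
kolik,Digestive system
durchfall,Digestive system
magengeschwür,Digestive system
kotwasser,Digestive system
verstopfung,Digestive system
gastritis,Digestive system
enteritis,Digestive system
schlundverstopfung,Digestive system
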