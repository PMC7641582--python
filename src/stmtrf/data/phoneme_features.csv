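phoneme,components,Voiced,Unvoiced,Bilabial,Labiodental/Dental,Alveolar,Velar,Plosive,Nasal,Fricative,Liquid,Front,Central,Back
P,,0,1,1,0,0,0,1,0,0,0,0,0,0
B,,1,0,1,0,0,0,1,0,0,0,0,0,0
T,,0,1,0,0,1,0,1,0,0,0,0,0,0
D,,1,0,0,0,1,0,1,0,0,0,0,0,0
K,,0,1,0,0,0,1,1,0,0,0,0,0,0
G,,1,0,0,0,0,1,1,0,0,0,0,0,0
M,,1,0,1,0,0,0,0,1,0,0,0,0,0
N,,1,0,0,0,1,0,0,1,0,0,0,0,0
NG,,1,0,0,0,0,1,0,1,0,0,0,0,0
F,,0,1,0,1,0,0,0,0,1,0,0,0,0
V,,1,0,0,1,0,0,0,0,1,0,0,0,0
TH,,0,1,0,1,0,0,0,0,1,0,0,0,0
DH,,1,0,0,1,0,0,0,0,1,0,0,0,0
S,,0,1,0,0,1,0,0,0,1,0,0,0,0
Z,,1,0,0,0,1,0,0,0,1,0,0,0,0
SH,,0,1,0,0,1,0,0,0,1,0,0,0,0
ZH,,1,0,0,0,1,0,0,0,1,0,0,0,0
HH,,0,1,0,0,0,0,0,0,1,0,0,0,0
L,,1,0,0,0,1,0,0,0,0,1,0,0,0
R,,1,0,0,0,1,0,0,0,0,1,0,0,0
W,,1,0,1,0,0,0,0,0,0,1,0,0,0
Y,,1,0,0,0,0,0,0,0,0,1,0,0,0
IY,,1,0,0,0,0,0,0,0,0,0,1,0,0
IH,,1,0,0,0,0,0,0,0,0,0,1,0,0
EH,,1,0,0,0,0,0,0,0,0,0,1,0,0
AE,,1,0,0,0,0,0,0,0,0,0,1,0,0
AH,,1,0,0,0,0,0,0,0,0,0,0,1,0
ER,,1,0,0,0,0,0,0,0,0,0,0,1,0
AA,,1,0,0,0,0,0,0,0,0,0,0,0,1
AO,,1,0,0,0,0,0,0,0,0,0,0,0,1
UH,,1,0,0,0,0,0,0,0,0,0,0,0,1
UW,,1,0,0,0,0,0,0,0,0,0,0,0,1
EY,EH+IY,,,,,,,,,,,,,
AY,AA+IY,,,,,,,,,,,,,
OY,AO+IH,,,,,,,,,,,,,
AW,AA+UH,,,,,,,,,,,,,
OW,AH+UH,,,,,,,,,,,,,
CH,T+SH,,,,,,,,,,,,,
JH,D+ZH,,,,,,,,,,,,,
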