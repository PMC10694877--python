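country,continent
US,North America
CA,North America
MX,North America
CU,North America
DO,North America
GT,North America
HN,North America
CR,North America
PA,North America
JM,North America
PR,North America
BR,South America
AR,South America
CL,South America
CO,South America
PE,South America
VE,South America
EC,South America
UY,South America
PY,South America
BO,South America
GB,Europe
DE,Europe
FR,Europe
IT,Europe
ES,Europe
PT,Europe
NL,Europe
BE,Europe
LU,Europe
IE,Europe
DK,Europe
SE,Europe
NO,Europe
FI,Europe
IS,Europe
CH,Europe
AT,Europe
PL,Europe
CZ,Europe
SK,Europe
HU,Europe
RO,Europe
BG,Europe
GR,Europe
HR,Europe
SI,Europe
RS,Europe
UA,Europe
RU,Europe
EE,Europe
LV,Europe
LT,Europe
MT,Europe
CY,Europe
CN,Asia
JP,Asia
KR,Asia
IN,Asia
ID,Asia
TH,Asia
VN,Asia
PH,Asia
MY,Asia
SG,Asia
TW,Asia
HK,Asia
IL,Asia
TR,Asia
SA,Asia
AE,Asia
IR,Asia
IQ,Asia
PK,Asia
BD,Asia
LK,Asia
KZ,Asia
ZA,Africa
EG,Africa
NG,Africa
KE,Africa
MA,Africa
DZ,Africa
TN,Africa
GH,Africa
ET,Africa
TZ,Africa
UG,Africa
SN,Africa
CM,Africa
CI,Africa
ZW,Africa
AU,Oceania
NZ,Oceania
FJ,Oceania
PG,Oceania
NC,Oceania
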