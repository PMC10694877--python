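ingredient,class
cefazolin,first/second-generation cephalosporins
cephradine,first/second-generation cephalosporins
cefadroxil,first/second-generation cephalosporins
cephalexin,first/second-generation cephalosporins
cefuroxime,first/second-generation cephalosporins
cefaclor,first/second-generation cephalosporins
cefoxitin,first/second-generation cephalosporins
ceftriaxone,third-generation cephalosporins
ceftazidime,third-generation cephalosporins
cefditoren,third-generation cephalosporins
cefotaxime,third-generation cephalosporins
cefixime,third-generation cephalosporins
cefdinir,third-generation cephalosporins
cefpodoxime,third-generation cephalosporins
cefepime,fourth-generation cephalosporins
cefiderocol,novel cephalosporins
ceftaroline,novel cephalosporins
ceftolozane-tazobactam,novel cephalosporins
amoxicillin,penicillins
ampicillin,penicillins
floxacillin,penicillins
penicillin,penicillins
piperacillin,penicillins
oxacillin,penicillins
nafcillin,penicillins
dicloxacillin,penicillins
amoxicillin-clavulanate,beta-lactamase inhibitors
ampicillin-sulbactam,beta-lactamase inhibitors
piperacillin-tazobactam,beta-lactamase inhibitors
ceftazidime-avibactam,beta-lactamase inhibitors
cefoperazone-sulbactam,beta-lactamase inhibitors
meropenem,carbapenems
imipenem-cilastatin,carbapenems
ertapenem,carbapenems
doripenem,carbapenems
clindamycin,lincomycins
lincomycin,lincomycins
ciprofloxacin,fluoroquinolones
levofloxacin,fluoroquinolones
moxifloxacin,fluoroquinolones
ofloxacin,fluoroquinolones
norfloxacin,fluoroquinolones
pazufloxacin,fluoroquinolones
erythromycin,erythromycins
azithromycin,erythromycins
clarithromycin,erythromycins
tobramycin,aminoglycosides
gentamicin,aminoglycosides
amikacin,aminoglycosides
streptomycin,aminoglycosides
tetracycline,tetracyclines
doxycycline,tetracyclines
minocycline,tetracyclines
tigecycline,tetracyclines
vancomycin,other antibiotics
metronidazole,other antibiotics
chloramphenicol,other antibiotics
rifabutin,other antibiotics
linezolid,other antibiotics
daptomycin,other antibiotics
trimethoprim-sulfamethoxazole,other antibiotics
amphotericin b,antifungal drugs
fluconazole,antifungal drugs
itraconazole,antifungal drugs
voriconazole,antifungal drugs
caspofungin,antifungal drugs
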