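verbatim,ingredient
AMOXICILLIN AND CLAVULANATE POTASSIUM,amoxicillin-clavulanate
AMOXICILLIN/CLAVULANIC ACID,amoxicillin-clavulanate
AUGMENTIN,amoxicillin-clavulanate
CO-AMOXICLAV,amoxicillin-clavulanate
AMPICILLIN AND SULBACTAM,ampicillin-sulbactam
UNASYN,ampicillin-sulbactam
PIPERACILLIN AND TAZOBACTAM,piperacillin-tazobactam
ZOSYN,piperacillin-tazobactam
TAZOCIN,piperacillin-tazobactam
CEFTAZIDIME AND AVIBACTAM,ceftazidime-avibactam
AVYCAZ,ceftazidime-avibactam
CEFOPERAZONE AND SULBACTAM,cefoperazone-sulbactam
SULPERAZON,cefoperazone-sulbactam
CEFTOLOZANE AND TAZOBACTAM,ceftolozane-tazobactam
ZERBAXA,ceftolozane-tazobactam
IMIPENEM AND CILASTATIN,imipenem-cilastatin
PRIMAXIN,imipenem-cilastatin
PAZUFLOXACIN MESILATE,pazufloxacin
CEFDITOREN PIVOXIL,cefditoren
ROCEPHIN,ceftriaxone
CLEOCIN,clindamycin
DALACIN,clindamycin
CIPRO,ciprofloxacin
LEVAQUIN,levofloxacin
AVELOX,moxifloxacin
ZITHROMAX,azithromycin
BIAXIN,clarithromycin
VANCOCIN,vancomycin
FLAGYL,metronidazole
DIFLUCAN,fluconazole
AMPHOTERICIN B LIPOSOMAL,amphotericin b
AMBISOME,amphotericin b
FUNGIZONE,amphotericin b
BACTRIM,trimethoprim-sulfamethoxazole
SEPTRA,trimethoprim-sulfamethoxazole
TRIMETHOPRIM AND SULFAMETHOXAZOLE,trimethoprim-sulfamethoxazole
ZYVOX,linezolid
CUBICIN,daptomycin
KEFLEX,cephalexin
ANCEF,cefazolin
MAXIPIME,cefepime
FETROJA,cefiderocol
TEFLARO,ceftaroline
MYCOBUTIN,rifabutin
VIBRAMYCIN,doxycycline
MINOCIN,minocycline
TYGACIL,tigecycline
TOBREX,tobramycin
MERREM,meropenem
INVANZ,ertapenem
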