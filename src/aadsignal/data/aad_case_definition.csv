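pt_code,pt_name
10009657,Clostridium difficile colitis
10037128,Pseudomembranous colitis
10052815,Antibiotic associated colitis
10058305,Clostridium colitis
10058852,Clostridium bacteraemia
10061043,Clostridial infection
10070027,Clostridium test positive
10078496,Clostridial sepsis
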