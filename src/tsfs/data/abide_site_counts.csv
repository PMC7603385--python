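site,asd,control
Caltech,19,18
CMU,14,13
KKI,20,28
Leuven,29,34
MaxMun,24,28
NYU,75,100
OHSU,12,14
OLIN,19,15
PITT,29,27
SBL,15,15
SDSU,14,22
Stanford,19,20
Trinity,22,25
UCLA,54,44
UM,66,74
USM,46,25
Yale,28,28
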