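at_code,emin_kcal,rmin_ang,provenance
N:=,-5.5,1.6,published
N1:,-4.0,1.6,published
N:,-4.5,1.6,placeholder
N2:,-4.0,1.6,placeholder
N::,-3.5,1.6,placeholder
N:#,-3.0,1.6,placeholder
ON,-3.0,1.5,placeholder
O1,-4.0,1.5,placeholder
OC1,-2.5,1.5,placeholder
OC2,-3.0,1.5,placeholder
OC=,-2.0,1.5,placeholder
OES,-2.0,1.5,placeholder
OFU,-2.5,1.5,placeholder
OH,-4.0,1.5,placeholder
O=S,-4.0,1.5,placeholder
OS,-4.5,1.5,placeholder
O=,-5.0,1.5,placeholder
O,-4.5,1.5,placeholder
GENERIC,-3.0,1.55,placeholder
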