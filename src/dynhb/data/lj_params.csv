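element,epsilon_kcal,sigma_ang,comment
H,0.016,1.20,approximate van der Waals well for nonpolar H
C,0.086,3.40,sp2/sp3 carbon average
N,0.170,3.25,nitrogen
O,0.210,2.96,oxygen
S,0.250,3.56,sulfur
P,0.200,3.74,phosphorus
F,0.061,2.94,fluorine
Cl,0.265,3.47,chlorine
Br,0.320,3.62,bromine
I,0.400,3.83,iodine
X,0.100,3.40,fallback for unparametrized elements
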