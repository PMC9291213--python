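priority,at_code,roles,smarts,comment
10,ON,A,"[OX1;$([OX1]~[#7])]","nitro/nitroso oxygen; before generic terminal O"
20,O=S,A,"[OX1;$([OX1]~[SX4])]","sulphone/sulfate/sulphonamide oxygen (S bears four connections)"
30,OS,A,"[OX1;$([OX1]~[SX3])]","sulphoxide/sulphinate oxygen (S bears three connections)"
40,O=,A,"[OX1;$([OX1]~[#15,#14,#33])]","terminal O on P/Si/As"
50,O,A,"[OX1;$([OX1]=[#6])]","sp2 carbonylic oxygen"
60,OFU,A,"[o]","aromatic furan/oxazole oxygen"
70,OH,A|D,"[OX2H1;$([OX2H1][c]),$([OX2H1][CX3]=[OX1])]","phenolic or carboxy hydroxyl"
80,O1,A|D,"[OX2H1]","aliphatic sp3 hydroxyl"
90,OES,A,"[OX2H0;$([OX2H0][CX3]=[OX1]),$([OX2H0][cX3]=[OX1])]","tetrahedral ester bridging oxygen; before ether codes"
100,OC=,A,"[OX2H0;$([OX2H0]([c])[c])]","diaryl ether oxygen"
110,OC2,A,"[OX2H0;$([OX2H0]([CX4])[CX4])]","dialkyl ether oxygen"
120,OC1,A,"[OX2H0;$([OX2H0][#6])]","remaining (mixed aliphatic/aryl) ether oxygen"
130,N:#,A,"[NX1;$([NX1]#*)]","sp nitrogen (nitrile/isonitrile terminal)"
140,N::,A,"[$([NX1;!$([NX1]#*)]),$([NX2-;$([NX2-]=*)])]","sp2 nitrogen with two lone pairs and one double bond"
150,N:=,A,"[nX2]","aromatic pyridine-type sp2 nitrogen"
160,N1:,A|D,"[NX3H1;!$([NX3H1]~[OX1])]","sp3 secondary nitrogen, one donatable hydrogen"
170,N2:,A|D,"[NX3H2;!$([NX3H2]~[OX1])]","sp3 primary nitrogen, up to two donatable hydrogens"
180,N:,A,"[NX3H0;!$([NX3H0]~[OX1]);!$([nX3])]","sp3 tertiary nitrogen"
900,H_polar,,"[#1;$([#1][#7,#8])]","hydrogen on N or O"
910,C_generic,,"[#6]","any carbon; carries no H-bond role"
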