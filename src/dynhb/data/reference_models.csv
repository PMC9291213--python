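at_code,role,n_atoms,n_lv,r2,q2,sdec,sdep,description
N:,A,6954,9,0.92,0.88,0.56,0.41,"sp3 (tertiary) nitrogen, accepting one H-bond"
N1:,A,3941,8,0.91,0.84,0.24,0.49,"sp3 (secondary) nitrogen, donating one hydrogen and accepting one H-bond"
N1:,D,4776,7,0.96,0.92,0.30,0.53,"sp3 (secondary) nitrogen, donating one hydrogen and accepting one H-bond"
N2:,A,3618,8,0.84,0.71,0.26,0.38,"sp3 (primary) nitrogen, donating up to two hydrogen and accepting one H-bond"
N2:,D,4895,7,0.95,0.92,0.30,0.41,"sp3 (primary) nitrogen, donating up to two hydrogen and accepting one H-bond"
ON,A,4907,8,0.82,0.69,0.26,0.38,"oxygen of nitro or nitroso group, accepting up to two H-bond"
N:=,A,27140,12,0.91,0.89,0.35,0.47,"sp2 (aromatic) nitrogen, accepting one H-bond"
N::,A,472,4,0.89,0.59,0.23,0.12,"sp2 nitrogen with two lone pairs and one double bond"
N:#,A,15798,10,0.72,0.66,0.29,0.32,"sp nitrogen"
O1,A,1367,6,0.86,0.66,0.30,0.55,"alcoholic oxygen atom in sp3 hydroxyl group, capable of donating one hydrogen and accepting up to two H-bonds"
O1,D,1392,7,0.87,0.65,0.29,0.50,"alcoholic oxygen atom in sp3 hydroxyl group, capable of donating one hydrogen and accepting up to two H-bonds"
OC1,A,12725,10,0.74,0.66,0.32,0.44,"aliphatic and aryl ether oxygen, accepting one H-bonds"
OC2,A,7100,8,0.81,0.73,0.30,0.44,"aliphatic ether oxygen, accepting two H-bonds"
OC=,A,2527,9,0.89,0.75,0.26,0.46,"aryl ether oxygen, accepting one H-bond"
OES,A,11501,10,0.82,0.76,0.28,0.39,"tetrahedral ester oxygen, not accepting H-bonds"
OFU,A,6114,9,0.88,0.81,0.26,0.47,"aromatic furan or oxazole oxygen, accepting one H-bond"
OH,A,4892,7,0.78,0.62,0.29,0.50,"phenolic and carboxy oxygen, capable of donating one hydrogen and accepting up to two H-bonds"
OH,D,4892,7,0.78,0.62,0.29,0.50,"phenolic and carboxy oxygen, capable of donating one hydrogen and accepting up to two H-bonds"
O=S,A,15886,10,0.84,0.81,0.24,0.37,"oxygen bonded only to one central S (sulphones, sulfates, unionized sulfate, sulphonamides), accepting two H-bonds"
OS,A,947,4,0.90,0.69,0.25,0.41,"oxygen bonded only to one central S (sulphoxides, unionized sulphonate esters, unionized alkyl sulphinates), accepting two H-bonds"
O=,A,13307,7,0.86,0.83,0.33,0.44,"oxygen bonded to one atom (e.g. phosphates arsenates silicates) and accepting up to two H-bonds"
O,A,7811,6,0.90,0.86,0.33,0.61,"sp2 carbonylic oxygen, accepting up to two H-bonds"
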