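target,ligands,crystals,pki_range
01-CA2,10,10,2.2
02-HIV-PR,22,12,5.1
03-CK2,16,16,1.9
04-AR,14,14,2.8
05-Cath-D,10,3,3.5
06-BACE1,16,16,3.6
07-JAK1,12,12,3.4
08-Trypsin,15,15,4.4
09-CDK2,31,31,3.6
10-MMP12,18,18,3.9
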