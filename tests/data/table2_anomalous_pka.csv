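# Published pKa values of the eight residues with anomalous ionization
# (never crossing half-protonation within the scanned pH 1-8 window).
residue,CpHMD,PROPKA,DeepKa,PB_A,H++
D37,< 1,4.9,3,0.3,2.9
E62,< 1,2.5,2.6,0.4,< 0
E71,< 1,1.1,4.1,0.5,4.6
D126,< 1,3.2,2.5,0.5,< 0
D127,> 8,7.4,5.5,3.8,6.6
D256,> 8,6,3.2,0.6,< 0
E296,> 8,9.6,7.3,8.9,9.4
D312,> 8,4.5,6.5,1.5,4.0
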