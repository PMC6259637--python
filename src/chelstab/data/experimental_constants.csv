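metal,ligand,logK1,logB2
Cu,glycine,8.57,15.63
Ni,glycine,6.15,11.15
Co,glycine,5.09,9.10
Fe,glycine,4.30,7.80
Mn,glycine,3.55,6.63
Cu,alanine,8.41,15.21
Ni,alanine,5.96,10.66
Co,alanine,4.83,8.55
Fe,alanine,,7.30
Mn,alanine,3.13,6.05
Cu,valine,7.93,14.45
Co,valine,4.57,8.24
Fe,valine,,6.80
Mn,valine,2.84,5.56
Cu,leucine,7.89,14.34
Ni,leucine,5.62,10.18
Co,leucine,4.52,8.16
Mn,leucine,2.78,5.45
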