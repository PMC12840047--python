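base_name	compound_class
(+)-Limonene	aromatic hydrocarbon
1,2-Ethanediol	alcohol
1-Butanol	alcohol
1-Butanol, 3-methyl-, acetate	ester
1-Hexanal	aldehyde
1-Hexanol	alcohol
1-Octen-3-ol	alcohol
1-Pentanol	alcohol
1-Propanol	alcohol
2,3-Bbutanedione	ketone
2,6-Dimethyl pyrazine	heterocyclic
2-Acetylpyridine	heterocyclic
2-Butanone	ketone
2-Heptanone	ketone
2-Hexanone	ketone
(E)-2-Hhexen-1-ol	alcohol
2-Methylbutanoic acid, methyl ester	ester
2-Methylpyrazine	heterocyclic
2-Nonanone	ketone
2-Octanone	ketone
2-Pentanone	ketone
2-Propanol	alcohol
3-Methyl butyl acetate	ester
Acetic acid	other
Acetic acid ethyl ester	ester
Acetophenone	ketone
α-Pinene	aromatic hydrocarbon
Benzaldehyde	aldehyde
Butanal	aldehyde
Butanoic acid, ethyl ester	ester
Cyclohexanone	ketone
Ethanol	alcohol
Ethyl acrylate	ester
Ethyl butanoate	ester
Ethyl hexanoate	ester
Ethyl octanoate	ester
Ethyl pentanoate	ester
Heptanal	aldehyde
n-Pentanal	aldehyde
Propanal	aldehyde
Styrene	aromatic hydrocarbon
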