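wavenumber,assignment
943,Phosphodiester region
959,Symmetric stretching vibration of v1 (PO4 3-)
974,OCH3 stretching in polysaccharides
1078,Phosphate I in RNA
1113,P-O-C symmetric stretching
1121,Symmetric phosphodiester stretching band RNA
1134,C-OH stretching band in oligosaccharide
1140,C-O stretching in phosphate and oligosaccharides
1142,C-O stretching in phosphate and oligosaccharides
1148,C-O stretching in carbohydrates
1153,Stretching vibrations of hydrogen-bonding C-OH groups
1159,v(C-O) of proteins and carbohydrates
1182,Amide III
1192,Collagen
1319,Amide III
1385,d(CH3)
1398,CH3 symmetric deformation
1423,vs(COO2) in polysaccharides or pectin
1477,d(CH2) of the methylene chains in lipids
1545,Amide II in proteins
1622,Peak of nucleic acids due to the base carbonyl stretching and ring breathing mode
1636,beta-sheet structure of Amide I
1668,Amide I (anti-parallel beta-sheet)
1798,v(C=C) in lipids
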