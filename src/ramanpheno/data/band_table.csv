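position,allocation
621,Phosphate backbone (DNA/RNA)
643,Tyrosine (ring breathing)
672,Phosphate backbone (DNA/RNA)
719,Cholesterol (steroid ring breathing)
751,Tryptophan (indole ring vibrations)
781,Phenylalanine
837,"Proteins (Amide III, in-plane N-H bending and C-N stretching)"
872,Saccharides
889,Glykogen
936,Proline
972,Phospholipids
1001,Phenylalanine
1031,Lipids
1065,C-C Stretching in lipids
1111,C-C Stretching in lipids
1125,Desoxyribose (DNA/RNA)
1143,Lipids
1156,Proteins (Amide III)
1172,Proteins (Amide III)
1207,Tryptophan
1259,Proteins (Amide III)
1301,CH2 Twisting in lipids
1314,CH2 Twisting and Wagging in lipids
1326,Guanine (DNA/RNA)
1338,Collagen fibers
1369,CH3 Deformation in lipids
1403,COO- groups (Carboxylates in amino acids)
1445,CH2 Deformation in lipids and proteins
1512,NADH
1524,Chromophores like cytochromes
1553,Proteins (Amide II)
1582,Chromophores like cytochromes
1618,Proteins (Amide I)
1657,"Proteins (Amide I, C=O Stretching)"
1745,Ester C=O Stretching (Triglycerides in lipids)
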