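pathway_id,pathway_name,members
map00970,Aminoacyl-tRNA biosynthesis,Ala;Gly;His;Tyr;Ile;Leu;Lys;Met;Phe;Thr;Trp;Val;Glu;Gln
map02010,ABC transporters,Ala;Gly;His;Ile;Leu;Lys;Met;Phe;Thr;Trp;Val;Glu;Gln;Bet;Cho;m-I;α-Glc;β-Glc
map00260,"Glycine, serine and threonine metabolism",Gly;Thr;Bet;Cho;Cr;Py
map00250,"Alanine, aspartate and glutamate metabolism",Ala;Glu;Gln;Py;Suc;Cit;Fum
map00620,Pyruvate metabolism,Py;Lac;Ace;Mal;Fum
map00052,Galactose metabolism,α-Glc;β-Glc;G;m-I
map00564,Glycerophospholipid metabolism,Cho;PC;GPC;G
map00280,"Valine, leucine and isoleucine degradation",Val;Leu;Ile;3-HB;AA;Suc
map00310,Lysine degradation,Lys;AA
map00340,Histidine metabolism,His;1-MH;Glu
map00730,Thiamine metabolism,Gly;Tyr
map00072,Synthesis and degradation of ketone bodies,3-HB;AA;Act
map00020,Citrate cycle (TCA cycle),Cit;Suc;Fum;Py
map00010,Glycolysis / Gluconeogenesis,α-Glc;β-Glc;Py;Lac;Ace
map00330,Arginine and proline metabolism,Cr;Glu;Gln;Py;Fum
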