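abbreviation,name,peaks,category,pathways
1-MH,1-Methylhistidine,7.06(s);7.78(s),nonessential_amino_acid,
3-HB,3-Hydroxybutyrate,1.20(d);2.31(dd);2.40(m);4.16(m),ketone_body,
Ace,Acetate,1.92(s),carboxylic_acid,
AA,Acetoacetate,2.28(s),ketone_body,
Act,Acetone,2.24(s),ketone_body,
Ala,Alanine,1.48(d),nonessential_amino_acid,
All,Allantoin,5.39(s),other,
Bet,Betaine,3.27(s);3.90(s),nonessential_amino_acid,
Cho,Choline,3.20(s),choline_derivative,
Cit,Citrate,2.53(d);2.67(d),glycolysis_glutaminolysis,
Cr,Creatine,3.04(s);3.93(s),nonessential_amino_acid,
Eth,Ethanol,1.18(t);3.61(q),alcohol,
For,Formate,8.46(s),carboxylic_acid,
Fum,Fumarate,6.52(s),carboxylic_acid,
Glu,Glutamate,2.08(m);2.11(m);2.35(m);3.75(t),glycolysis_glutaminolysis,
Gln,Glutamine,2.14(m);2.45(m);3.75(t),glycolysis_glutaminolysis,
G,Glycerol,3.55(m);3.66(dd);3.78(m),alcohol,
GPC,Glycerolphosphocholine,3.23(s);4.33(m),choline_derivative,
Gly,Glycine,3.56(s),nonessential_amino_acid,
His,Histidine,7.08(s);7.82(s),nonessential_amino_acid,
HOD,Residual water signal,4.76(br),region_marker,
IB,Isobutyrate,1.07(d),carboxylic_acid,
Ile,Isoleucine,0.94(t);1.01(d),essential_amino_acid,
L1,LDL,0.86(br);1.28(br),lipid,
L2,VLDL,0.89(br);1.30(br);1.58(br),lipid,
L3,Unsaturated fatty acid,2.04(br);2.24(br);2.76(br);5.31(br),lipid,
Lac,Lactate,1.33(d);4.11(q),glycolysis_glutaminolysis,
Leu,Leucine,0.96(d),essential_amino_acid,
Lys,Lysine,1.46(m);1.73(m);1.91(m);3.03(m);3.76(t),essential_amino_acid,
Mal,Malonate,3.11(s),carboxylic_acid,
Met,Methionine,2.14(s);2.63(t),essential_amino_acid,
MG,Methylguanidine,2.83(s);3.36(s),other,
Mol,Methanol,3.36(s),alcohol,
m-I,myo-Inositol,3.52(dd);3.61(dd);4.07(m),alcohol,
NAG,N-acetyl glycoprotein,2.03(s),other,
Phe,Phenylalanine,7.32(d);7.37(t);7.42(dd),essential_amino_acid,
PC,Phosphocholine,3.21(s),choline_derivative,
Py,Pyruvate,2.37(s),glycolysis_glutaminolysis,
Suc,Succinate,2.40(s),glycolysis_glutaminolysis,
Thr,Threonine,1.33(d);4.26(m),essential_amino_acid,
TMA,Trimethylamine,2.89(s),other,
Trp,Tryptophan,7.27(m);7.30(s);7.54(d);7.73(d),essential_amino_acid,
Tyr,Tyrosine,6.90(d);7.19(d),nonessential_amino_acid,
Urea,Urea,5.80(br),region_marker,
Val,Valine,0.99(d);1.04(d),essential_amino_acid,
α-Glc,α-Glucose,3.42(t);3.54(dd);3.71(t);3.73(m);3.84(m);5.24(d),glycolysis_glutaminolysis,
β-Glc,β-Glucose,3.24(ddb);3.41(t);3.46(m);3.49(t);3.90(dd);4.65(d),glycolysis_glutaminolysis,
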