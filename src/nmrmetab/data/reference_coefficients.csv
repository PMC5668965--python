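abbreviation,metabolite,bxpc3_vs_sw1990,panc1_vs_sw1990,panc1_vs_bxpc3
α-Glc,α-Glucose,-0.788,-0.631,
β-Glc,β-Glucose,-0.735,-0.842,
Cit,Citrate,0.817,0.921,
Glu,Glutamate,0.808,0.747,-0.789
Gln,Glutamine,0.767,0.856,
Lac,Lactate,0.906,0.905,
Py,Pyruvate,-0.880,,0.793
Suc,Succinate,,,
Ace,Acetate,,,
For,Formate,,,
Fum,Fumarate,,,
IB,Isobutyrate,,,-0.709
Mal,Malonate,,,-0.648
Eth,Ethanol,0.879,,-0.804
Mol,Methanol,0.702,0.760,0.667
m-I,myo-Inositol,0.889,0.817,-0.877
G,Glycerol,0.935,0.784,-0.916
L1,LDL,-0.899,-0.847,0.912
L2,VLDL,-0.774,0.720,0.921
L3,Unsaturated fatty acid,-0.899,-0.847,0.912
3-HB,3-Hydroxybutyrate,0.747,,-0.636
AA,Acetoacetate,,,
Act,Acetone,-0.760,,0.912
Cho,Choline,,-0.836,-0.841
GPC,Glycerolphosphocholine,0.671,-0.912,-0.894
PC,Phosphocholine,0.736,-0.832,-0.892
1-MH,1-Methylhistidine,,,-0.651
Ala,Alanine,0.750,0.778,
Bet,Betaine,0.812,0.834,-0.769
Cr,Creatine,0.930,0.826,-0.849
Gly,Glycine,0.871,0.674,
His,Histidine,0.776,0.602,
Tyr,Tyrosine,0.832,0.859,
Ile,Isoleucine,0.749,0.795,
Leu,Leucine,0.707,0.775,
Lys,Lysine,0.886,0.822,-0.780
Met,Methionine,,0.645,
Phe,Phenylalanine,0.878,0.813,-0.642
Thr,Threonine,0.630,0.794,0.730
Trp,Tryptophan,0.846,0.847,-0.673
Val,Valine,0.839,0.858,
MG,Methylguanidine,0.650,0.732,
All,Allantoin,-0.687,,
NAG,N-acetyl glycoprotein,,0.661,0.914
TMA,Trimethylamine,-0.855,0.750,0.782
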