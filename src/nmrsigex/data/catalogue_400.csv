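metabolite,multiplet_id,center_ppm,pattern,J_hz,protons,rel_intensities,raster_file,shift_tolerance_ppm,exclude_from_classification,base_conc
alanine,alanine_1.509,1.509,doublet,7.2,3,,,0.005,False,0.45
alanine,alanine_3.810,3.81,quartet,7.2,1,,,0.005,False,0.45
arginine,arginine_3.230,3.23,triplet,6.8,2,,,0.005,False,0.12
arginine,arginine_1.680,1.68,triplet,7.2,2,,,0.005,False,0.12
asparagine,asparagine_2.950,2.95,double_doublet,16.9;7.6,1,,,0.005,False,0.1
aspartate,aspartate_2.702,2.702,double_doublet,17.4;3.7,1,,,0.005,False,0.1
aspartate,aspartate_2.810,2.81,double_doublet,17.4;3.7,1,,,0.005,False,0.1
cysteine,cysteine_3.075,3.075,double_doublet,14.4;4.3,1,,,0.005,False,0.12
glutamine,glutamine_2.450,2.45,triplet,7.6,2,,,0.005,False,0.55
glutamate,glutamate_2.350,2.35,triplet,7.5,2,,,0.005,False,0.25
glycine,glycine_3.561,3.561,singlet,,2,,,0.005,False,0.3
histidine,histidine_7.060,7.06,singlet,,1,,,0.005,False,0.1
isoleucine,isoleucine_1.010,1.01,doublet,7,3,,,0.005,False,0.12
leucine,leucine_0.961,0.961,doublet,6.3,6,,,0.005,False,0.18
lysine,lysine_3.012,3.012,triplet,7.6,2,,,0.005,False,0.2
methionine,methionine_2.138,2.138,singlet,,3,,,0.005,False,0.1
phenylalanine,phenylalanine_7.420,7.42,doublet,7.7,2,,,0.005,False,0.1
proline,proline_4.130,4.13,double_doublet,8.6;6.4,1,,,0.005,False,0.2
proline,proline_3.340,3.34,triplet,6.8,2,,,0.005,False,0.2
serine,serine_3.945,3.945,double_doublet,12.3;3.9,1,,,0.005,False,0.15
threonine,threonine_1.318,1.318,doublet,6.6,3,,,0.005,False,0.15
threonine,threonine_4.250,4.25,double_doublet,6.6;4.9,1,,,0.005,False,0.15
tryptophan,tryptophan_7.720,7.72,doublet,8,1,,,0.005,False,0.1
tyrosine,tyrosine_3.055,3.055,double_doublet,14.7;5.1,1,,,0.005,False,0.1
tyrosine,tyrosine_6.900,6.9,doublet,8.5,2,,,0.005,False,0.1
valine,valine_0.984,0.984,doublet,7,3,,,0.005,False,0.25
valine,valine_1.031,1.031,doublet,7,3,,,0.005,False,0.25
alpha-D-glucopyranose,alpha-D-glucopyranose_5.230,5.23,doublet,3.8,1,,,0.005,False,1.6
beta-D-glucopyranose,beta-D-glucopyranose_3.240,3.24,double_doublet,9.4;8,1,,,0.005,False,2.4
myo-inositol,myo-inositol_4.054,4.054,triplet,2.8,1,,,0.005,False,0.1
acetate,acetate_1.918,1.918,singlet,,3,,,0.005,False,0.15
acetoacetate,acetoacetate_2.270,2.27,singlet,,3,,,0.005,False,0.1
alpha-ketoglutarate,alpha-ketoglutarate_3.001,3.001,triplet,6.9,2,,,0.005,False,0.1
beta-hydroxybutyrate,beta-hydroxybutyrate_1.200,1.2,doublet,6.3,3,,,0.005,False,0.15
citrate,citrate_2.566,2.566,doublet,15.6,2,0.8;1.2,,0.005,False,0.15
citrate,citrate_2.717,2.717,doublet,15.6,2,1.2;0.8,,0.005,False,0.15
lactate,lactate_1.330,1.33,doublet,7,3,,,0.005,False,1.5
lactate,lactate_4.110,4.11,quartet,7,1,,,0.005,False,1.5
pyruvate,pyruvate_2.370,2.37,singlet,,3,,,0.005,False,0.12
succinate,succinate_2.410,2.41,singlet,,4,,,0.005,False,0.1
creatine,creatine_3.029,3.029,singlet,,3,,,0.005,False,0.1
creatine,creatine_3.913,3.913,singlet,,2,,,0.005,False,0.1
creatinine,creatinine_3.045,3.045,singlet,,3,,,0.005,False,0.08
creatinine,creatinine_4.060,4.06,singlet,,2,,,0.005,False,0.08
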