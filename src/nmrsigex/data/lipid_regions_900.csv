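lipid_id,resonance_label,ppm_lo,ppm_hi
lip_CH3,CH3-(CH2)n fatty acid chain,0.78,1.0
lip_CH2n_a,-(CH2)n- fatty acid chain (upfield),1.18,1.3
lip_CH2n_b,-(CH2)n- fatty acid chain (downfield),1.3,1.45
lip_CH2CH2CO,-CH2-CH2-C=O fatty acid chain,1.48,1.64
lip_lysyl,lysyl,1.66,1.78
lip_allylic,-CH2-CH=CH- fatty acid chain,1.9,2.02
lip_NAG,CH3 in N-acetylated glycoproteins,2.02,2.1
lip_CH2CO,-CH2-C=O fatty acid chain,2.18,2.32
lip_diallylic,=CH-CH2-CH= fatty acid chain,2.68,2.86
lip_olefinic,-CH=CH- fatty acid chain,5.2,5.45
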