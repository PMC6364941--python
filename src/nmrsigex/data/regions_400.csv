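region_id,ppm_lo,ppm_hi,annotation,category
r001,0.3,0.3699,,unknown
r002,0.3699,0.4398,,unknown
r003,0.4398,0.5097,,unknown
r004,0.5097,0.5796,,unknown
r005,0.5796,0.6495,,unknown
r006,0.6495,0.7194,,unknown
r007,0.7194,0.7893,,unknown
r008,0.7893,0.8592,,unknown
r009,0.8592,0.9291,,unknown
r010,0.9291,1.0638,isoleucine+leucine+valine,mixed
r011,1.0638,1.1681,,unknown
r012,1.1681,1.2319,beta-hydroxybutyrate,metabolite
r013,1.2319,1.2858,,unknown
r014,1.2858,1.3628,lactate+threonine,mixed
r015,1.3628,1.4194,,unknown
r016,1.4194,1.476,,unknown
r017,1.476,1.542,alanine,metabolite
r018,1.542,1.638,,unknown
r019,1.638,1.722,arginine,metabolite
r020,1.722,1.808,,unknown
r021,1.808,1.894,,unknown
r022,1.894,1.942,acetate,metabolite
r023,1.942,2.028,,unknown
r024,2.028,2.114,,unknown
r025,2.114,2.162,methionine,metabolite
r026,2.162,2.246,,unknown
r027,2.246,2.294,acetoacetate,metabolite
r028,2.3073,2.493,glutamate+glutamine+pyruvate+succinate,mixed
r029,2.5225,2.6095,citrate,metabolite
r030,2.6095,2.6516,,unknown
r031,2.6516,2.8604,aspartate+citrate,mixed
r032,2.8604,2.8954,,unknown
r033,2.8954,3.1224,alpha-ketoglutarate+asparagine+creatine+creatinine+cysteine+lysine+tyrosine,mixed
r034,3.1224,3.189,,unknown
r035,3.189,3.2858,arginine+beta-D-glucopyranose,mixed
r036,3.299,3.381,proline,metabolite
r037,3.381,3.459,,unknown
r038,3.459,3.537,,unknown
r039,3.537,3.585,glycine,metabolite
r040,3.585,3.672,,unknown
r041,3.672,3.759,,unknown
r042,3.759,3.861,alanine,metabolite
r043,3.889,3.9892,creatine+serine,mixed
r044,3.9892,4.023,,unknown
r045,4.023,4.1728,creatinine+lactate+myo-inositol+proline,mixed
r046,4.1728,4.2116,,unknown
r047,4.2116,4.2884,threonine,metabolite
r048,4.2884,4.3589,,unknown
r049,4.3589,4.4295,,unknown
r050,4.4295,4.5,,unknown
r051,5.1,5.2013,,unknown
r052,5.2013,5.2588,alpha-D-glucopyranose,metabolite
r053,5.2588,5.3318,,unknown
r054,5.3318,5.4048,,unknown
r055,5.4048,5.4778,,unknown
r056,5.4778,5.5509,,unknown
r057,5.5509,5.6239,,unknown
r058,5.6239,5.6969,,unknown
r059,5.6969,5.7699,,unknown
r060,5.7699,5.843,,unknown
r061,5.843,5.916,,unknown
r062,5.916,5.989,,unknown
r063,5.989,6.0621,,unknown
r064,6.0621,6.1351,,unknown
r065,6.1351,6.2081,,unknown
r066,6.2081,6.2811,,unknown
r067,6.2811,6.3542,,unknown
r068,6.3542,6.4272,,unknown
r069,6.4272,6.5002,,unknown
r070,6.5002,6.5733,,unknown
r071,6.5733,6.6463,,unknown
r072,6.6463,6.7193,,unknown
r073,6.7193,6.7923,,unknown
r074,6.7923,6.8654,,unknown
r075,6.8654,6.9346,tyrosine,metabolite
r076,6.9346,7.036,,unknown
r077,7.036,7.084,histidine,metabolite
r078,7.084,7.1596,,unknown
r079,7.1596,7.2352,,unknown
r080,7.2352,7.3108,,unknown
r081,7.3108,7.3864,,unknown
r082,7.3864,7.4536,phenylalanine,metabolite
r083,7.4536,7.5311,,unknown
r084,7.5311,7.6085,,unknown
r085,7.6085,7.686,,unknown
r086,7.686,7.754,tryptophan,metabolite
r087,7.754,7.8268,,unknown
r088,7.8268,7.8995,,unknown
r089,7.8995,7.9722,,unknown
r090,7.9722,8.045,,unknown
r091,8.045,8.1177,,unknown
r092,8.1177,8.1905,,unknown
r093,8.1905,8.2632,,unknown
r094,8.2632,8.336,,unknown
r095,8.336,8.4088,,unknown
r096,8.4088,8.4815,,unknown
r097,8.4815,8.5542,,unknown
r098,8.5542,8.627,,unknown
r099,8.627,8.6998,,unknown
r100,8.6998,8.7725,,unknown
r101,8.7725,8.8452,,unknown
r102,8.8452,8.918,,unknown
r103,8.918,8.9908,,unknown
r104,8.9908,9.0635,,unknown
r105,9.0635,9.1362,,unknown
r106,9.1362,9.209,,unknown
r107,9.209,9.2818,,unknown
r108,9.2818,9.3545,,unknown
r109,9.3545,9.4273,,unknown
r110,9.4273,9.5,,unknown
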