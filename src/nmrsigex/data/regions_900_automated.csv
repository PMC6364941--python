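region_id,ppm_lo,ppm_hi,annotation,category
r001,0.3,0.4077,,unknown
r002,0.4077,0.5154,,unknown
r003,0.5154,0.623,,unknown
r004,0.623,0.7307,,unknown
r005,0.7307,0.8384,,unknown
r006,0.8384,0.9461,,unknown
r007,0.9461,1.0463,isoleucine+leucine+valine,mixed
r008,1.0463,1.1851,,unknown
r009,1.1851,1.2149,beta-hydroxybutyrate,metabolite
r010,1.2149,1.3029,,unknown
r011,1.3029,1.3453,lactate+threonine,mixed
r012,1.3453,1.4936,,unknown
r013,1.4936,1.5244,alanine,metabolite
r014,1.5244,1.6606,,unknown
r015,1.6606,1.6994,arginine,metabolite
r016,1.6994,1.803,,unknown
r017,1.803,1.9066,,unknown
r018,1.9066,1.9294,acetate,metabolite
r019,1.9294,2.028,,unknown
r020,2.028,2.1266,,unknown
r021,2.1266,2.1494,methionine,metabolite
r022,2.1494,2.2586,,unknown
r023,2.2586,2.2814,acetoacetate,metabolite
r024,2.2814,2.3302,,unknown
r025,2.3302,2.3814,glutamate+pyruvate,mixed
r026,2.3986,2.4214,succinate,metabolite
r027,2.4301,2.4699,glutamine,metabolite
r028,2.4699,2.5459,,unknown
r029,2.5459,2.5861,citrate,metabolite
r030,2.5861,2.6788,,unknown
r031,2.6788,2.7371,aspartate+citrate,mixed
r032,2.7371,2.7868,,unknown
r033,2.7868,2.8332,aspartate,metabolite
r034,2.8332,2.9249,,unknown
r035,2.9249,2.9751,asparagine,metabolite
r036,2.9819,3.0968,alpha-ketoglutarate+creatine+creatinine+cysteine+lysine+tyrosine,mixed
r037,3.0968,3.1936,,unknown
r038,3.1936,3.2714,arginine+beta-D-glucopyranose+betaine+choline,mixed
r039,3.2714,3.321,,unknown
r040,3.321,3.359,proline,metabolite
r041,3.359,3.4543,,unknown
r042,3.4543,3.5496,,unknown
r043,3.5496,3.5724,glycine,metabolite
r044,3.5724,3.6795,,unknown
r045,3.6795,3.7866,,unknown
r046,3.7866,3.8334,alanine,metabolite
r047,3.8334,3.9016,,unknown
r048,3.9016,3.9244,creatine,metabolite
r049,3.9246,3.9654,serine,metabolite
r050,3.9654,4.0394,,unknown
r051,4.0394,4.0714,creatinine+myo-inositol,mixed
r052,4.0869,4.1498,lactate+proline,mixed
r053,4.1498,4.2322,,unknown
r054,4.2322,4.2678,threonine,metabolite
r055,4.2678,4.3839,,unknown
r056,4.3839,4.5,,unknown
r057,5.1,5.2164,,unknown
r058,5.2164,5.2436,alpha-D-glucopyranose,metabolite
r059,5.2436,5.3461,,unknown
r060,5.3461,5.4486,,unknown
r061,5.4486,5.5511,,unknown
r062,5.5511,5.6536,,unknown
r063,5.6536,5.7561,,unknown
r064,5.7561,5.8587,,unknown
r065,5.8587,5.9612,,unknown
r066,5.9612,6.0637,,unknown
r067,6.0637,6.1662,,unknown
r068,6.1662,6.2687,,unknown
r069,6.2687,6.3712,,unknown
r070,6.3712,6.4738,,unknown
r071,6.4738,6.5763,,unknown
r072,6.5763,6.6788,,unknown
r073,6.6788,6.7813,,unknown
r074,6.7813,6.8838,,unknown
r075,6.8838,6.9162,tyrosine,metabolite
r076,6.9162,7.0486,,unknown
r077,7.0486,7.0714,histidine,metabolite
r078,7.0714,7.1824,,unknown
r079,7.1824,7.2933,,unknown
r080,7.2933,7.4043,,unknown
r081,7.4043,7.4357,phenylalanine,metabolite
r082,7.4357,7.5252,,unknown
r083,7.5252,7.6146,,unknown
r084,7.6146,7.7041,,unknown
r085,7.7041,7.7359,tryptophan,metabolite
r086,7.7359,7.8339,,unknown
r087,7.8339,7.9319,,unknown
r088,7.9319,8.0299,,unknown
r089,8.0299,8.1279,,unknown
r090,8.1279,8.2259,,unknown
r091,8.2259,8.3239,,unknown
r092,8.3239,8.4219,,unknown
r093,8.4219,8.5199,,unknown
r094,8.5199,8.6179,,unknown
r095,8.6179,8.716,,unknown
r096,8.716,8.814,,unknown
r097,8.814,8.912,,unknown
r098,8.912,9.01,,unknown
r099,9.01,9.108,,unknown
r100,9.108,9.206,,unknown
r101,9.206,9.304,,unknown
r102,9.304,9.402,,unknown
r103,9.402,9.5,,unknown
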