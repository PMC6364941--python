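region_id,ppm_lo,ppm_hi,annotation,category
r001,0.3,0.392,,unknown
r002,0.392,0.484,,unknown
r003,0.484,0.5759,,unknown
r004,0.5759,0.6679,,unknown
r005,0.6679,0.7599,,unknown
r006,0.7599,0.8519,,unknown
r007,0.8519,0.9438,,unknown
r008,0.9438,1.0486,isoleucine+leucine+valine,mixed
r009,1.0486,1.1828,,unknown
r010,1.1828,1.2172,beta-hydroxybutyrate,metabolite
r011,1.2172,1.3007,,unknown
r012,1.3007,1.3476,lactate+threonine,mixed
r013,1.3476,1.4194,,unknown
r014,1.4194,1.4913,,unknown
r015,1.4913,1.5267,alanine,metabolite
r016,1.5267,1.6583,,unknown
r017,1.6583,1.7017,arginine,metabolite
r018,1.7017,1.803,,unknown
r019,1.803,1.9043,,unknown
r020,1.9043,1.9317,acetate,metabolite
r021,1.9317,2.028,,unknown
r022,2.028,2.1243,,unknown
r023,2.1243,2.1517,methionine,metabolite
r024,2.1517,2.2563,,unknown
r025,2.2563,2.2837,acetoacetate,metabolite
r026,2.328,2.3837,glutamate+pyruvate,mixed
r027,2.3963,2.4237,succinate,metabolite
r028,2.4279,2.4721,glutamine,metabolite
r029,2.4721,2.5437,,unknown
r030,2.5437,2.5883,citrate,metabolite
r031,2.5883,2.6766,,unknown
r032,2.6766,2.7393,aspartate+citrate,mixed
r033,2.7393,2.7846,,unknown
r034,2.7846,2.8354,aspartate,metabolite
r035,2.8354,2.9227,,unknown
r036,2.9227,2.9773,asparagine,metabolite
r037,2.9797,3.0991,alpha-ketoglutarate+creatine+creatinine+cysteine+lysine+tyrosine,mixed
r038,3.0991,3.1913,,unknown
r039,3.1913,3.2737,arginine+beta-D-glucopyranose+betaine+choline,mixed
r040,3.2737,3.3188,,unknown
r041,3.3188,3.3612,proline,metabolite
r042,3.3612,3.4543,,unknown
r043,3.4543,3.5473,,unknown
r044,3.5473,3.5747,glycine,metabolite
r045,3.5747,3.6795,,unknown
r046,3.6795,3.7843,,unknown
r047,3.7843,3.8357,alanine,metabolite
r048,3.8357,3.8993,,unknown
r049,3.8993,3.9677,creatine+serine,mixed
r050,3.9677,4.0372,,unknown
r051,4.0372,4.0737,creatinine+myo-inositol,mixed
r052,4.0847,4.152,lactate+proline,mixed
r053,4.152,4.2299,,unknown
r054,4.2299,4.2701,threonine,metabolite
r055,4.2701,4.385,,unknown
r056,4.385,4.5,,unknown
r057,5.1,5.2142,,unknown
r058,5.2142,5.2458,alpha-D-glucopyranose,metabolite
r059,5.2458,5.342,,unknown
r060,5.342,5.4382,,unknown
r061,5.4382,5.5345,,unknown
r062,5.5345,5.6307,,unknown
r063,5.6307,5.7269,,unknown
r064,5.7269,5.8231,,unknown
r065,5.8231,5.9194,,unknown
r066,5.9194,6.0156,,unknown
r067,6.0156,6.1118,,unknown
r068,6.1118,6.208,,unknown
r069,6.208,6.3043,,unknown
r070,6.3043,6.4005,,unknown
r071,6.4005,6.4967,,unknown
r072,6.4967,6.5929,,unknown
r073,6.5929,6.6892,,unknown
r074,6.6892,6.7854,,unknown
r075,6.7854,6.8816,,unknown
r076,6.8816,6.9184,tyrosine,metabolite
r077,6.9184,7.0463,,unknown
r078,7.0463,7.0737,histidine,metabolite
r079,7.0737,7.1831,,unknown
r080,7.1831,7.2926,,unknown
r081,7.2926,7.4021,,unknown
r082,7.4021,7.4379,phenylalanine,metabolite
r083,7.4379,7.5259,,unknown
r084,7.5259,7.6139,,unknown
r085,7.6139,7.7019,,unknown
r086,7.7019,7.7381,tryptophan,metabolite
r087,7.7381,7.8308,,unknown
r088,7.8308,7.9236,,unknown
r089,7.9236,8.0163,,unknown
r090,8.0163,8.109,,unknown
r091,8.109,8.2018,,unknown
r092,8.2018,8.2945,,unknown
r093,8.2945,8.3872,,unknown
r094,8.3872,8.48,,unknown
r095,8.48,8.5727,,unknown
r096,8.5727,8.6654,,unknown
r097,8.6654,8.7582,,unknown
r098,8.7582,8.8509,,unknown
r099,8.8509,8.9436,,unknown
r100,8.9436,9.0363,,unknown
r101,9.0363,9.1291,,unknown
r102,9.1291,9.2218,,unknown
r103,9.2218,9.3145,,unknown
r104,9.3145,9.4073,,unknown
r105,9.4073,9.5,,unknown
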