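pathway,gene,weight
Wnt,gene0510,-0.1321
Wnt,gene0382,0.6404
Wnt,gene0045,-0.5357
Wnt,gene0009,0.3616
Wnt,gene0302,0.9471
Wnt,gene0363,-0.7037
Wnt,gene0335,-0.6233
Wnt,gene0561,0.0413
Wnt,gene0236,-0.2188
Wnt,gene0514,-1.2459
VEGF,gene0507,-0.5443
VEGF,gene0105,-0.3163
VEGF,gene0048,1.0425
VEGF,gene0179,-0.1285
VEGF,gene0003,-0.6652
VEGF,gene0074,0.3515
VEGF,gene0154,0.094
VEGF,gene0369,-0.7435
VEGF,gene0482,-0.4577
VEGF,gene0588,0.2202
Trail,gene0504,-0.2092
Trail,gene0413,-0.1592
Trail,gene0347,0.2147
Trail,gene0432,0.3554
Trail,gene0253,-0.1296
Trail,gene0291,0.784
Trail,gene0318,-1.2591
Trail,gene0214,1.5139
Trail,gene0431,0.7813
Trail,gene0356,0.2645
TNFa,gene0196,1.458
TNFa,gene0534,1.9603
TNFa,gene0029,1.3151
TNFa,gene0050,0.3574
TNFa,gene0189,-0.0045
TNFa,gene0143,0.6565
TNFa,gene0402,0.3951
TNFa,gene0201,0.4299
TNFa,gene0536,-1.1841
TNFa,gene0477,-0.6617
TGFb,gene0342,-1.1698
TGFb,gene0242,1.7394
TGFb,gene0373,0.329
TGFb,gene0348,-0.2586
TGFb,gene0534,1.3204
TGFb,gene0119,0.6334
TGFb,gene0381,0.052
TGFb,gene0063,0.6837
TGFb,gene0245,-0.6179
TGFb,gene0264,1.822
PI3K,gene0209,-0.6615
PI3K,gene0597,0.935
PI3K,gene0500,2.0024
PI3K,gene0454,0.1885
PI3K,gene0138,-0.3776
PI3K,gene0471,-1.0911
PI3K,gene0449,0.6304
PI3K,gene0426,0.5812
PI3K,gene0079,-0.7546
PI3K,gene0437,1.6891
p53,gene0522,1.5744
p53,gene0008,-0.4328
p53,gene0496,0.2498
p53,gene0574,1.0315
p53,gene0220,-0.5855
p53,gene0533,-1.3412
p53,gene0196,0.5027
p53,gene0139,0.9897
p53,gene0582,-1.0744
p53,gene0159,0.873
NFkB,gene0089,-0.7131
NFkB,gene0558,0.621
NFkB,gene0109,0.3864
NFkB,gene0368,-0.5816
NFkB,gene0186,-0.0757
NFkB,gene0009,0.2021
NFkB,gene0539,-0.7584
NFkB,gene0557,1.421
NFkB,gene0374,0.8437
NFkB,gene0040,1.1649
MAPK,gene0523,0.8441
MAPK,gene0579,0.0756
MAPK,gene0163,-0.135
MAPK,gene0145,-0.7695
MAPK,gene0075,0.115
MAPK,gene0074,0.2585
MAPK,gene0515,-1.0298
MAPK,gene0332,-1.043
MAPK,gene0272,0.3587
MAPK,gene0173,1.3225
JAK/STAT,gene0495,1.0418
JAK/STAT,gene0375,1.4023
JAK/STAT,gene0049,-2.3653
JAK/STAT,gene0331,1.2287
JAK/STAT,gene0566,0.4238
JAK/STAT,gene0087,0.3712
JAK/STAT,gene0564,0.3194
JAK/STAT,gene0025,-0.3589
JAK/STAT,gene0515,-0.1089
JAK/STAT,gene0497,-0.8037
Hypoxia,gene0065,-0.2888
Hypoxia,gene0047,0.0835
Hypoxia,gene0570,-0.5106
Hypoxia,gene0421,-0.0115
Hypoxia,gene0022,0.3007
Hypoxia,gene0518,-0.1061
Hypoxia,gene0258,-2.3982
Hypoxia,gene0257,0.5131
Hypoxia,gene0415,-0.53
Hypoxia,gene0465,-0.2362
Estrogen,gene0305,-0.0498
Estrogen,gene0517,0.0866
Estrogen,gene0381,1.6473
Estrogen,gene0206,0.9175
Estrogen,gene0038,0.0477
Estrogen,gene0109,0.9167
Estrogen,gene0164,0.6132
Estrogen,gene0400,-0.1522
Estrogen,gene0577,1.0289
Estrogen,gene0448,-1.935
Androgen,gene0337,-0.2045
Androgen,gene0084,-1.0429
Androgen,gene0492,-0.2003
Androgen,gene0100,-0.4369
Androgen,gene0346,-0.4766
Androgen,gene0336,1.389
Androgen,gene0469,-0.4743
Androgen,gene0315,-1.9443
Androgen,gene0315,1.0868
Androgen,gene0589,-0.0506
EGFR,gene0326,1.6433
EGFR,gene0463,-1.2826
EGFR,gene0579,-0.4726
EGFR,gene0191,0.5863
EGFR,gene0347,-0.6134
EGFR,gene0117,-1.6051
EGFR,gene0530,0.8061
EGFR,gene0577,-0.4764
EGFR,gene0408,-1.2926
EGFR,gene0232,-0.4718
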