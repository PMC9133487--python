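# Synthetic whole-blood hemoglobin optical coefficients, mm^-1, 450-650 nm at 1 nm.
# SYNTHETIC reconstruction: pchip interpolation of hand-set anchor points chosen to
# reproduce the qualitative landmark features of standard tabulated Hb/HbO2
# compilations at ~150 g/L total hemoglobin: HbO2 alpha/beta bands near 577/542 nm,
# the single deoxy-Hb band near 556 nm, isosbestic-like crossings near 500, 525,
# 548, 571 and 587 nm, and the strong deoxy excess beyond 600 nm. Magnitudes are
# order-of-magnitude realistic but NOT metrologically traceable; forward and inverse
# models in this package use this same table, so saturation recovery is exact by
# construction. mu_s columns follow a smooth power law ~lambda^-0.7 (HCT~45%).
lambda_nm,mu_a_hbo2,mu_a_hb,mu_s_hbo2,mu_s_hb
450,33.6000,55.3000,92.0651,97.8192
451,32.5218,53.3780,91.9222,97.6673
452,31.4586,51.4840,91.7798,97.5160
453,30.4129,49.6216,91.6379,97.3653
454,29.3871,47.7939,91.4966,97.2151
455,28.3834,46.0044,91.3558,97.0655
456,27.4043,44.2563,91.2155,96.9164
457,26.4521,42.5529,91.0757,96.7679
458,25.5292,40.8977,90.9365,96.6200
459,24.6379,39.2940,90.7977,96.4726
460,23.7807,37.7450,90.6595,96.3257
461,22.9599,36.2541,90.5218,96.1794
462,22.1778,34.8246,90.3846,96.0336
463,21.4368,33.4599,90.2479,95.8884
464,20.7393,32.1633,90.1117,95.7437
465,20.0877,30.9381,89.9760,95.5995
466,19.4842,29.7877,89.8408,95.4559
467,18.9314,28.7153,89.7061,95.3127
468,18.4315,27.7243,89.5719,95.1701
469,17.9869,26.8181,89.4382,95.0281
470,17.6000,26.0000,89.3049,94.8865
471,17.2537,25.2485,89.1721,94.7454
472,16.9283,24.5379,89.0399,94.6049
473,16.6224,23.8655,88.9080,94.4648
474,16.3345,23.2284,88.7767,94.3253
475,16.0632,22.6237,88.6458,94.1862
476,15.8070,22.0486,88.5154,94.0476
477,15.5646,21.5002,88.3855,93.9096
478,15.3344,20.9756,88.2560,93.7720
479,15.1150,20.4720,88.1270,93.6349
480,14.9049,19.9865,87.9984,93.4983
481,14.7028,19.5163,87.8703,93.3622
482,14.5071,19.0586,87.7427,93.2266
483,14.3164,18.6103,87.6155,93.0915
484,14.1292,18.1688,87.4887,92.9568
485,13.9442,17.7311,87.3624,92.8226
486,13.7598,17.2944,87.2365,92.6888
487,13.5747,16.8557,87.1111,92.5556
488,13.3873,16.4124,86.9861,92.4228
489,13.1962,15.9614,86.8616,92.2904
490,13.0000,15.5000,86.7374,92.1585
491,12.7882,15.0008,86.6137,92.0271
492,12.5578,14.4543,86.4905,91.8961
493,12.3183,13.8838,86.3676,91.7656
494,12.0795,13.3130,86.2452,91.6355
495,11.8509,12.7655,86.1232,91.5059
496,11.6423,12.2647,86.0016,91.3767
497,11.4633,11.8342,85.8805,91.2480
498,11.3234,11.4976,85.7597,91.1197
499,11.2325,11.2783,85.6394,90.9918
500,11.2000,11.2000,85.5194,90.8644
501,11.2164,11.2267,85.3999,90.7374
502,11.2629,11.3021,85.2808,90.6109
503,11.3350,11.4190,85.1621,90.4847
504,11.4286,11.5703,85.0438,90.3590
505,11.5393,11.7488,84.9259,90.2337
506,11.6629,11.9475,84.8083,90.1088
507,11.7950,12.1590,84.6912,89.9844
508,11.9314,12.3764,84.5745,89.8604
509,12.0679,12.5924,84.4581,89.7368
510,12.2000,12.8000,84.3422,89.6136
511,12.3288,13.0128,84.2266,89.4908
512,12.4601,13.2470,84.1114,89.3684
513,12.5974,13.4995,83.9966,89.2464
514,12.7438,13.7669,83.8822,89.1248
515,12.9028,14.0459,83.7681,89.0036
516,13.0775,14.3332,83.6545,88.8829
517,13.2712,14.6256,83.5412,88.7625
518,13.4874,14.9197,83.4282,88.6425
519,13.7292,15.2123,83.3157,88.5229
520,14.0000,15.5000,83.2035,88.4037
521,14.3603,15.7829,83.0917,88.2849
522,14.8538,16.0643,82.9802,88.1665
523,15.4590,16.3463,82.8691,88.0484
524,16.1542,16.6308,82.7584,87.9308
525,16.9177,16.9198,82.6480,87.8135
526,17.7277,17.2152,82.5380,87.6966
527,18.5626,17.5189,82.4283,87.5801
528,19.4008,17.8330,82.3190,87.4639
529,20.2205,18.1594,82.2100,87.3482
530,21.0000,18.5000,82.1014,87.2328
531,21.7694,18.8599,81.9932,87.1177
532,22.5656,19.2415,81.8853,87.0031
533,23.3771,19.6432,81.7777,86.8888
534,24.1924,20.0633,81.6705,86.7749
535,25.0000,20.5000,81.5636,86.6613
536,25.8713,20.9865,81.4570,86.5481
537,26.8139,21.5262,81.3508,86.4352
538,27.7208,22.0726,81.2449,86.3227
539,28.4852,22.5794,81.1394,86.2106
540,29.0000,23.0000,81.0342,86.0988
541,29.3386,23.3056,80.9293,85.9874
542,29.5000,23.6000,80.8247,85.8763
543,29.2553,23.9798,80.7205,85.7656
544,28.6772,24.3999,80.6166,85.6552
545,28.0000,24.8000,80.5131,85.5451
546,27.2071,25.1592,80.4098,85.4354
547,26.1996,25.5016,80.3069,85.3261
548,25.0886,25.8344,80.2043,85.2170
549,23.9851,26.1648,80.1020,85.1083
550,23.0000,26.5000,80.0000,85.0000
551,22.0915,26.8737,79.8983,84.8920
552,21.1811,27.2810,79.7970,84.7843
553,20.3249,27.6715,79.6960,84.6770
554,19.5792,27.9947,79.5952,84.5699
555,19.0000,28.2000,79.4948,84.4632
556,18.5178,28.3245,79.3947,84.3569
557,18.0580,28.4341,79.2949,84.2508
558,17.6693,28.5214,79.1954,84.1451
559,17.4004,28.5791,79.0962,84.0397
560,17.3000,28.6000,78.9973,83.9346
561,17.4673,28.5371,78.8987,83.8299
562,17.9100,28.3714,78.8004,83.7254
563,18.5390,28.1371,78.7024,83.6213
564,19.2653,27.8686,78.6047,83.5175
565,20.0000,27.6000,78.5073,83.4140
566,20.8230,27.3222,78.4102,83.3108
567,21.8189,26.9997,78.3133,83.2079
568,22.9053,26.6273,78.2168,83.1053
569,24.0000,26.2000,78.1205,83.0031
570,25.1646,25.6953,78.0246,82.9011
571,26.4537,25.1002,77.9289,82.7995
572,27.7746,24.4240,77.8335,82.6981
573,29.0344,23.6757,77.7384,82.5971
574,30.1405,22.8647,77.6436,82.4963
575,31.0000,22.0000,77.5490,82.3958
576,31.7263,20.9317,77.4548,82.2957
577,32.1000,19.8000,77.3608,82.1958
578,31.7859,18.8267,77.2671,82.0963
579,31.0051,17.9082,77.1736,81.9970
580,30.0000,17.0000,77.0805,81.8980
581,28.4559,16.0598,76.9876,81.7993
582,26.1316,15.1008,76.8949,81.7009
583,23.3793,14.1619,76.8026,81.6028
584,20.5514,13.2820,76.7105,81.5049
585,18.0000,12.5000,76.6187,81.4074
586,15.5334,11.7704,76.5271,81.3101
587,12.9151,11.0552,76.4359,81.2131
588,10.4300,10.4048,76.3448,81.1164
589,8.3633,9.8696,76.2541,81.0200
590,7.0000,9.5000,76.1636,80.9238
591,6.1256,9.2561,76.0734,80.8280
592,5.3340,9.0576,75.9834,80.7324
593,4.6227,8.8946,75.8937,80.6370
594,3.9895,8.7569,75.8042,80.5420
595,3.4321,8.6345,75.7150,80.4472
596,2.9481,8.5173,75.6261,80.3527
597,2.5352,8.3954,75.5374,80.2585
598,2.1911,8.2585,75.4489,80.1645
599,1.9135,8.0968,75.3607,80.0708
600,1.7000,7.9000,75.2728,79.9773
601,1.5244,7.6430,75.1851,79.8842
602,1.3621,7.3192,75.0976,79.7912
603,1.2138,6.9468,75.0104,79.6986
604,1.0797,6.5438,74.9235,79.6062
605,0.9603,6.1285,74.8368,79.5141
606,0.8561,5.7188,74.7503,79.4222
607,0.7676,5.3331,74.6641,79.3306
608,0.6951,4.9893,74.5781,79.2392
609,0.6391,4.7055,74.4924,79.1481
610,0.6000,4.5000,74.4069,79.0573
611,0.5709,4.3449,74.3216,78.9667
612,0.5442,4.1999,74.2366,78.8764
613,0.5200,4.0645,74.1518,78.7863
614,0.4978,3.9383,74.0672,78.6964
615,0.4777,3.8206,73.9829,78.6068
616,0.4595,3.7109,73.8988,78.5175
617,0.4429,3.6088,73.8149,78.4284
618,0.4278,3.5137,73.7313,78.3395
619,0.4140,3.4251,73.6479,78.2509
620,0.4014,3.3424,73.5647,78.1625
621,0.3898,3.2651,73.4818,78.0744
622,0.3790,3.1928,73.3991,77.9865
623,0.3689,3.1248,73.3166,77.8989
624,0.3593,3.0608,73.2343,77.8115
625,0.3500,3.0000,73.1523,77.7243
626,0.3408,2.9408,73.0705,77.6374
627,0.3317,2.8819,72.9889,77.5507
628,0.3227,2.8234,72.9075,77.4642
629,0.3138,2.7655,72.8263,77.3780
630,0.3050,2.7084,72.7454,77.2920
631,0.2964,2.6522,72.6647,77.2062
632,0.2880,2.5972,72.5842,77.1207
633,0.2798,2.5435,72.5039,77.0354
634,0.2718,2.4912,72.4238,76.9503
635,0.2641,2.4407,72.3440,76.8655
636,0.2568,2.3919,72.2643,76.7808
637,0.2497,2.3452,72.1849,76.6964
638,0.2430,2.3006,72.1057,76.6123
639,0.2367,2.2584,72.0267,76.5283
640,0.2308,2.2188,71.9479,76.4446
641,0.2253,2.1818,71.8693,76.3611
642,0.2203,2.1478,71.7909,76.2778
643,0.2157,2.1167,71.7127,76.1948
644,0.2117,2.0890,71.6348,76.1119
645,0.2083,2.0646,71.5570,76.0293
646,0.2054,2.0438,71.4794,75.9469
647,0.2031,2.0268,71.4021,75.8647
648,0.2014,2.0137,71.3249,75.7827
649,0.2003,2.0047,71.2480,75.7010
650,0.2000,2.0000,71.1712,75.6194
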