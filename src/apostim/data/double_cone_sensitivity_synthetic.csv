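wavelength_nm,sensitivity
350,0.000000
351,0.000000
352,0.000000
353,0.000000
354,0.000000
355,0.000000
356,0.000000
357,0.000000
358,0.000000
359,0.000000
360,0.000000
361,0.000000
362,0.000000
363,0.000000
364,0.000000
365,0.000000
366,0.000000
367,0.000000
368,0.000000
369,0.000000
370,0.000000
371,0.000000
372,0.000000
373,0.000000
374,0.000000
375,0.000000
376,0.000000
377,0.000000
378,0.000000
379,0.000000
380,0.000000
381,0.000001
382,0.000001
383,0.000001
384,0.000001
385,0.000001
386,0.000001
387,0.000001
388,0.000001
389,0.000002
390,0.000002
391,0.000002
392,0.000002
393,0.000003
394,0.000003
395,0.000004
396,0.000004
397,0.000005
398,0.000005
399,0.000006
400,0.000007
401,0.000008
402,0.000009
403,0.000010
404,0.000011
405,0.000013
406,0.000014
407,0.000016
408,0.000018
409,0.000021
410,0.000024
411,0.000027
412,0.000030
413,0.000034
414,0.000039
415,0.000044
416,0.000049
417,0.000056
418,0.000063
419,0.000071
420,0.000080
421,0.000091
422,0.000102
423,0.000115
424,0.000130
425,0.000146
426,0.000165
427,0.000185
428,0.000209
429,0.000235
430,0.000264
431,0.000297
432,0.000333
433,0.000374
434,0.000421
435,0.000472
436,0.000530
437,0.000594
438,0.000666
439,0.000747
440,0.000836
441,0.000937
442,0.001049
443,0.001173
444,0.001312
445,0.001467
446,0.001640
447,0.001832
448,0.002046
449,0.002283
450,0.002547
451,0.002840
452,0.003165
453,0.003526
454,0.003926
455,0.004369
456,0.004860
457,0.005402
458,0.006003
459,0.006666
460,0.007398
461,0.008205
462,0.009096
463,0.010076
464,0.011155
465,0.012342
466,0.013645
467,0.015075
468,0.016642
469,0.018359
470,0.020237
471,0.022288
472,0.024528
473,0.026969
474,0.029626
475,0.032515
476,0.035652
477,0.039052
478,0.042733
479,0.046712
480,0.051005
481,0.055631
482,0.060605
483,0.065945
484,0.071667
485,0.077788
486,0.084321
487,0.091281
488,0.098681
489,0.106532
490,0.114843
491,0.123623
492,0.132877
493,0.142608
494,0.152818
495,0.163505
496,0.174666
497,0.186295
498,0.198381
499,0.210914
500,0.223880
501,0.237261
502,0.251039
503,0.265193
504,0.279699
505,0.294533
506,0.309669
507,0.325078
508,0.340732
509,0.356603
510,0.372659
511,0.388872
512,0.405212
513,0.421648
514,0.438152
515,0.454695
516,0.471250
517,0.487789
518,0.504288
519,0.520721
520,0.537066
521,0.553301
522,0.569404
523,0.585357
524,0.601141
525,0.616740
526,0.632137
527,0.647319
528,0.662272
529,0.676983
530,0.691442
531,0.705638
532,0.719561
533,0.733202
534,0.746555
535,0.759610
536,0.772362
537,0.784804
538,0.796931
539,0.808737
540,0.820218
541,0.831369
542,0.842185
543,0.852664
544,0.862802
545,0.872595
546,0.882040
547,0.891134
548,0.899875
549,0.908261
550,0.916288
551,0.923956
552,0.931262
553,0.938203
554,0.944780
555,0.950990
556,0.956832
557,0.962305
558,0.967408
559,0.972140
560,0.976501
561,0.980490
562,0.984107
563,0.987353
564,0.990227
565,0.992729
566,0.994861
567,0.996624
568,0.998017
569,0.999044
570,0.999704
571,1.000000
572,0.999934
573,0.999508
574,0.998725
575,0.997587
576,0.996097
577,0.994258
578,0.992074
579,0.989549
580,0.986687
581,0.983491
582,0.979966
583,0.976116
584,0.971948
585,0.967465
586,0.962673
587,0.957578
588,0.952185
589,0.946501
590,0.940532
591,0.934283
592,0.927762
593,0.920976
594,0.913931
595,0.906635
596,0.899094
597,0.891317
598,0.883310
599,0.875082
600,0.866640
601,0.857993
602,0.849148
603,0.840113
604,0.830897
605,0.821508
606,0.811955
607,0.802245
608,0.792387
609,0.782390
610,0.772263
611,0.762012
612,0.751648
613,0.741179
614,0.730613
615,0.719958
616,0.709223
617,0.698417
618,0.687547
619,0.676621
620,0.665649
621,0.654637
622,0.643594
623,0.632528
624,0.621446
625,0.610356
626,0.599265
627,0.588181
628,0.577111
629,0.566062
630,0.555040
631,0.544053
632,0.533107
633,0.522208
634,0.511363
635,0.500577
636,0.489857
637,0.479208
638,0.468635
639,0.458144
640,0.447740
641,0.437427
642,0.427210
643,0.417094
644,0.407083
645,0.397180
646,0.387391
647,0.377718
648,0.368164
649,0.358734
650,0.349429
651,0.340253
652,0.331209
653,0.322299
654,0.313524
655,0.304888
656,0.296391
657,0.288036
658,0.279824
659,0.271757
660,0.263834
661,0.256058
662,0.248429
663,0.240947
664,0.233614
665,0.226429
666,0.219392
667,0.212504
668,0.205764
669,0.199172
670,0.192727
671,0.186430
672,0.180278
673,0.174272
674,0.168410
675,0.162692
676,0.157115
677,0.151680
678,0.146385
679,0.141227
680,0.136206
681,0.131321
682,0.126569
683,0.121948
684,0.117457
685,0.113094
686,0.108858
687,0.104745
688,0.100754
689,0.096884
690,0.093131
691,0.089494
692,0.085971
693,0.082559
694,0.079256
695,0.076060
696,0.072969
697,0.069981
698,0.067093
699,0.064302
700,0.061608
701,0.059006
702,0.056496
703,0.054075
704,0.051740
705,0.049490
706,0.047322
707,0.045234
708,0.043224
709,0.041290
710,0.039429
711,0.037640
712,0.035920
713,0.034267
714,0.032679
715,0.031155
716,0.029692
717,0.028288
718,0.026942
719,0.025651
720,0.024414
721,0.023229
722,0.022095
723,0.021008
724,0.019969
725,0.018975
726,0.018024
727,0.017115
728,0.016247
729,0.015417
730,0.014626
731,0.013870
732,0.013149
733,0.012461
734,0.011805
735,0.011181
736,0.010585
737,0.010018
738,0.009479
739,0.008965
740,0.008477
741,0.008012
742,0.007570
743,0.007151
744,0.006752
745,0.006374
746,0.006015
747,0.005674
748,0.005350
749,0.005044
750,0.004753
751,0.004478
752,0.004217
753,0.003970
754,0.003736
755,0.003515
756,0.003306
757,0.003109
758,0.002922
759,0.002745
760,0.002579
761,0.002421
762,0.002273
763,0.002133
764,0.002000
765,0.001876
766,0.001758
767,0.001648
768,0.001544
769,0.001446
770,0.001353
771,0.001267
772,0.001185
773,0.001108
774,0.001036
775,0.000968
776,0.000905
777,0.000845
778,0.000789
779,0.000737
780,0.000687
781,0.000641
782,0.000598
783,0.000557
784,0.000519
785,0.000484
786,0.000450
787,0.000419
788,0.000390
789,0.000363
790,0.000338
791,0.000314
792,0.000292
793,0.000271
794,0.000252
795,0.000234
796,0.000217
797,0.000201
798,0.000187
799,0.000173
800,0.000160
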