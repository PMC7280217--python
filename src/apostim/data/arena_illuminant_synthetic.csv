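wavelength_nm,relative_radiance
350,0.383397
351,0.387508
352,0.391625
353,0.395745
354,0.399870
355,0.403997
356,0.408128
357,0.412261
358,0.416397
359,0.420534
360,0.424672
361,0.428812
362,0.432952
363,0.437092
364,0.441233
365,0.445372
366,0.449511
367,0.453649
368,0.457785
369,0.461919
370,0.466051
371,0.470180
372,0.474306
373,0.478429
374,0.482548
375,0.486663
376,0.490773
377,0.494879
378,0.498979
379,0.503075
380,0.507164
381,0.511248
382,0.515325
383,0.519395
384,0.523458
385,0.527514
386,0.531562
387,0.535603
388,0.539635
389,0.543658
390,0.547673
391,0.551679
392,0.555675
393,0.559662
394,0.563638
395,0.567605
396,0.571560
397,0.575505
398,0.579439
399,0.583362
400,0.587273
401,0.591173
402,0.595060
403,0.598935
404,0.602798
405,0.606647
406,0.610484
407,0.614307
408,0.618117
409,0.621914
410,0.625696
411,0.629464
412,0.633218
413,0.636957
414,0.640682
415,0.644392
416,0.648086
417,0.651765
418,0.655429
419,0.659077
420,0.662709
421,0.666324
422,0.669924
423,0.673507
424,0.677074
425,0.680624
426,0.684156
427,0.687672
428,0.691171
429,0.694652
430,0.698115
431,0.701561
432,0.704989
433,0.708399
434,0.711791
435,0.715165
436,0.718520
437,0.721857
438,0.725175
439,0.728475
440,0.731755
441,0.735017
442,0.738260
443,0.741483
444,0.744687
445,0.747872
446,0.751037
447,0.754183
448,0.757309
449,0.760415
450,0.763501
451,0.766567
452,0.769614
453,0.772640
454,0.775646
455,0.778632
456,0.781598
457,0.784543
458,0.787468
459,0.790372
460,0.793256
461,0.796119
462,0.798961
463,0.801783
464,0.804584
465,0.807364
466,0.810123
467,0.812861
468,0.815579
469,0.818275
470,0.820951
471,0.823605
472,0.826238
473,0.828851
474,0.831442
475,0.834012
476,0.836561
477,0.839088
478,0.841595
479,0.844080
480,0.846544
481,0.848987
482,0.851408
483,0.853809
484,0.856188
485,0.858545
486,0.860882
487,0.863197
488,0.865491
489,0.867764
490,0.870016
491,0.872246
492,0.874456
493,0.876644
494,0.878810
495,0.880956
496,0.883081
497,0.885184
498,0.887266
499,0.889328
500,0.891368
501,0.893387
502,0.895385
503,0.897362
504,0.899318
505,0.901254
506,0.903168
507,0.905062
508,0.906934
509,0.908786
510,0.910618
511,0.912428
512,0.914218
513,0.915987
514,0.917736
515,0.919464
516,0.921172
517,0.922860
518,0.924526
519,0.926173
520,0.927799
521,0.929406
522,0.930992
523,0.932557
524,0.934103
525,0.935629
526,0.937135
527,0.938621
528,0.940087
529,0.941533
530,0.942960
531,0.944367
532,0.945754
533,0.947122
534,0.948470
535,0.949799
536,0.951109
537,0.952399
538,0.953670
539,0.954922
540,0.956155
541,0.957369
542,0.958564
543,0.959740
544,0.960898
545,0.962036
546,0.963156
547,0.964258
548,0.965341
549,0.966406
550,0.967452
551,0.968480
552,0.969489
553,0.970481
554,0.971455
555,0.972410
556,0.973348
557,0.974268
558,0.975170
559,0.976055
560,0.976922
561,0.977771
562,0.978603
563,0.979418
564,0.980216
565,0.980996
566,0.981759
567,0.982506
568,0.983235
569,0.983947
570,0.984643
571,0.985322
572,0.985985
573,0.986631
574,0.987260
575,0.987873
576,0.988470
577,0.989051
578,0.989616
579,0.990164
580,0.990697
581,0.991214
582,0.991715
583,0.992201
584,0.992671
585,0.993125
586,0.993564
587,0.993988
588,0.994396
589,0.994790
590,0.995168
591,0.995531
592,0.995880
593,0.996213
594,0.996532
595,0.996836
596,0.997126
597,0.997401
598,0.997662
599,0.997908
600,0.998141
601,0.998359
602,0.998563
603,0.998753
604,0.998930
605,0.999092
606,0.999241
607,0.999376
608,0.999498
609,0.999607
610,0.999702
611,0.999783
612,0.999852
613,0.999907
614,0.999950
615,0.999979
616,0.999996
617,1.000000
618,0.999991
619,0.999970
620,0.999936
621,0.999890
622,0.999831
623,0.999761
624,0.999678
625,0.999583
626,0.999476
627,0.999357
628,0.999226
629,0.999083
630,0.998929
631,0.998763
632,0.998586
633,0.998397
634,0.998197
635,0.997986
636,0.997764
637,0.997530
638,0.997285
639,0.997030
640,0.996764
641,0.996487
642,0.996199
643,0.995900
644,0.995591
645,0.995272
646,0.994942
647,0.994602
648,0.994252
649,0.993891
650,0.993521
651,0.993140
652,0.992750
653,0.992350
654,0.991940
655,0.991520
656,0.991091
657,0.990652
658,0.990204
659,0.989746
660,0.989280
661,0.988804
662,0.988318
663,0.987824
664,0.987321
665,0.986808
666,0.986287
667,0.985758
668,0.985219
669,0.984672
670,0.984116
671,0.983552
672,0.982979
673,0.982398
674,0.981809
675,0.981211
676,0.980606
677,0.979992
678,0.979371
679,0.978741
680,0.978104
681,0.977458
682,0.976805
683,0.976145
684,0.975477
685,0.974801
686,0.974118
687,0.973427
688,0.972730
689,0.972025
690,0.971312
691,0.970593
692,0.969867
693,0.969133
694,0.968393
695,0.967646
696,0.966892
697,0.966131
698,0.965364
699,0.964590
700,0.963810
701,0.963023
702,0.962229
703,0.961430
704,0.960624
705,0.959812
706,0.958993
707,0.958169
708,0.957338
709,0.956502
710,0.955660
711,0.954811
712,0.953957
713,0.953097
714,0.952232
715,0.951361
716,0.950484
717,0.949602
718,0.948714
719,0.947821
720,0.946923
721,0.946019
722,0.945110
723,0.944196
724,0.943277
725,0.942352
726,0.941423
727,0.940489
728,0.939549
729,0.938605
730,0.937656
731,0.936703
732,0.935745
733,0.934782
734,0.933814
735,0.932842
736,0.931866
737,0.930885
738,0.929899
739,0.928910
740,0.927916
741,0.926917
742,0.925915
743,0.924908
744,0.923898
745,0.922883
746,0.921865
747,0.920842
748,0.919815
749,0.918785
750,0.917751
751,0.916713
752,0.915672
753,0.914626
754,0.913578
755,0.912525
756,0.911469
757,0.910410
758,0.909347
759,0.908281
760,0.907211
761,0.906138
762,0.905062
763,0.903983
764,0.902900
765,0.901815
766,0.900726
767,0.899634
768,0.898539
769,0.897442
770,0.896341
771,0.895238
772,0.894131
773,0.893022
774,0.891910
775,0.890796
776,0.889678
777,0.888558
778,0.887436
779,0.886311
780,0.885183
781,0.884053
782,0.882921
783,0.881786
784,0.880648
785,0.879509
786,0.878367
787,0.877223
788,0.876076
789,0.874928
790,0.873777
791,0.872624
792,0.871469
793,0.870312
794,0.869153
795,0.867992
796,0.866830
797,0.865665
798,0.864498
799,0.863330
800,0.862159
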