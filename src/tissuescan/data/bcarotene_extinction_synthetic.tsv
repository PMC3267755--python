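# bcarotene extinction synthetic
# SYNTHETIC parametric stand-in (Gaussian mixture), not measured data;
# replace via a user library directory to use measured spectra.
# columns: wavelength_nm	value (extinction mm^-1 per unit concentration)
340.0	9.3099816e-06
342.0	1.5429632e-05
344.0	2.5294923e-05
346.0	4.1013351e-05
348.0	6.5762883e-05
350.0	0.00010426912
352.0	0.00016345982
354.0	0.0002533453
356.0	0.00038817896
358.0	0.00058795418
360.0	0.00088029099
362.0	0.0013027554
364.0	0.0019056335
366.0	0.002755148
368.0	0.0039370578
370.0	0.0055605173
372.0	0.007761993
374.0	0.01070895
376.0	0.01460293
378.0	0.019681551
380.0	0.026218911
382.0	0.034523827
384.0	0.044935385
386.0	0.057815343
388.0	0.073537107
390.0	0.092471224
392.0	0.11496765
394.0	0.14133539
396.0	0.17182055
398.0	0.20658403
400.0	0.24568059
402.0	0.28904098
404.0	0.33645902
406.0	0.38758512
408.0	0.44192764
410.0	0.49886259
412.0	0.55765193
414.0	0.6174696
416.0	0.67743397
418.0	0.73664461
420.0	0.79422107
422.0	0.84934097
424.0	0.90127496
426.0	0.94941636
428.0	0.99330391
430.0	1.0326366
432.0	1.0672804
434.0	1.0972673
436.0	1.1227865
438.0	1.1441707
440.0	1.1618749
442.0	1.1764524
444.0	1.1885243
446.0	1.1987457
448.0	1.207767
450.0	1.2161906
452.0	1.2245251
454.0	1.2331382
456.0	1.2422107
458.0	1.2516975
460.0	1.2612986
462.0	1.2704463
464.0	1.2783133
466.0	1.2838438
468.0	1.2858102
470.0	1.2828922
472.0	1.2737738
474.0	1.2572515
476.0	1.2323422
478.0	1.1983813
480.0	1.1550999
482.0	1.1026724
484.0	1.0417285
486.0	0.97332812
488.0	0.89890035
490.0	0.82015363
492.0	0.73896562
494.0	0.65726388
496.0	0.5769089
498.0	0.49958989
500.0	0.4267417
502.0	0.35948821
504.0	0.29861428
506.0	0.24456522
508.0	0.19747011
510.0	0.1571833
512.0	0.1233379
514.0	0.095404557
516.0	0.072749804
518.0	0.054689385
520.0	0.040533314
522.0	0.029621029
524.0	0.021346212
526.0	0.015171959
528.0	0.010637644
530.0	0.0073592218
532.0	0.0050248096
534.0	0.0033872566
536.0	0.0022551733
538.0	0.001483552
540.0	0.00096478678
542.0	0.00062059537
544.0	0.00039509905
546.0	0.00024912839
548.0	0.00015569875
550.0	9.6524444e-05
552.0	5.940717e-05
554.0	3.6328939e-05
556.0	2.2091917e-05
558.0	1.336944e-05
560.0	8.0572643e-06
562.0	4.8383959e-06
564.0	2.89626e-06
566.0	1.7286605e-06
568.0	1.0288684e-06
570.0	6.106059e-07
572.0	3.6126436e-07
574.0	2.1301689e-07
576.0	1.2512753e-07
578.0	7.3188651e-08
580.0	4.2606759e-08
582.0	2.4674576e-08
584.0	1.4208851e-08
586.0	8.132479e-09
588.0	4.62463e-09
590.0	2.612021e-09
592.0	1.4648663e-09
594.0	8.1552336e-10
596.0	4.5061463e-10
598.0	2.4707786e-10
600.0	1.3442035e-10
602.0	7.2552678e-11
604.0	3.8847533e-11
606.0	2.0633231e-11
608.0	1.087035e-11
610.0	5.6803618e-12
612.0	2.9440991e-12
614.0	1.5134346e-12
616.0	7.7161899e-13
618.0	3.9018019e-13
620.0	1.9568024e-13
622.0	9.7329747e-14
624.0	4.8013041e-14
626.0	2.349019e-14
628.0	1.1397946e-14
630.0	5.4850278e-15
632.0	2.6178379e-15
634.0	1.2391334e-15
636.0	5.8170735e-16
638.0	2.7083332e-16
640.0	1.2505775e-16
642.0	5.7270373e-17
644.0	2.6011194e-17
646.0	1.1716594e-17
648.0	5.2342361e-18
650.0	2.3190816e-18
652.0	1.0190361e-18
654.0	4.4409296e-19
656.0	1.9194155e-19
658.0	8.2276331e-20
660.0	3.497773e-20
662.0	1.4747524e-20
664.0	6.1667649e-21
666.0	2.5574459e-21
668.0	1.0518803e-21
670.0	4.2907872e-22
672.0	1.7358749e-22
674.0	6.964832e-23
676.0	2.7714922e-23
678.0	1.0937737e-23
680.0	4.2810674e-24
682.0	1.6618333e-24
684.0	6.3978438e-25
686.0	2.4428151e-25
688.0	9.250354e-26
690.0	3.4740567e-26
692.0	1.293976e-26
694.0	4.779983e-27
696.0	1.7512061e-27
698.0	6.3629567e-28
700.0	2.2929335e-28
702.0	8.1947318e-29
704.0	2.9046166e-29
706.0	1.0210657e-29
708.0	3.5598305e-30
710.0	1.2308801e-30
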