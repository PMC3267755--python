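# hb extinction synthetic
# SYNTHETIC parametric stand-in (Gaussian mixture), not measured data;
# reproduces oxy-Hb's Soret band (~415 nm), the broad inter-band
# absorption through 450-520 nm, the Q bands (~542/577 nm) and the
# near-transparent red; replace via a user library directory to use
# measured spectra.
# columns: wavelength_nm	value (extinction mm^-1 per mg/mL)
340.0	0.18034562
342.0	0.20141293
344.0	0.22313864
346.0	0.2452198
348.0	0.267314
350.0	0.2890481
352.0	0.31002971
354.0	0.32986139
356.0	0.34815762
358.0	0.36456452
360.0	0.37878252
362.0	0.39059207
364.0	0.39988277
366.0	0.40668595
368.0	0.41121059
370.0	0.41388178
372.0	0.41537978
374.0	0.41667626
376.0	0.41906227
378.0	0.42416056
380.0	0.43391287
382.0	0.45053197
384.0	0.47640866
386.0	0.51396686
388.0	0.56546487
390.0	0.63274939
392.0	0.71697798
394.0	0.81833681
396.0	0.93578909
398.0	1.0668954
400.0	1.2077463
402.0	1.353041
404.0	1.4963288
406.0	1.6304112
408.0	1.7478765
410.0	1.8417161
412.0	1.905953
414.0	1.9362067
416.0	1.9301195
418.0	1.8875887
420.0	1.810772
422.0	1.7038654
424.0	1.5726869
426.0	1.4241211
428.0	1.2654981
430.0	1.1039849
432.0	0.94605533
434.0	0.7970918
436.0	0.6611443
438.0	0.54085091
440.0	0.43750116
442.0	0.35120952
444.0	0.28115816
446.0	0.22586842
448.0	0.18346555
450.0	0.15191079
452.0	0.12918528
454.0	0.11342024
456.0	0.10297583
458.0	0.096476348
460.0	0.092812229
462.0	0.091119604
464.0	0.090747211
466.0	0.091218382
468.0	0.092193567
470.0	0.093436767
472.0	0.094787471
474.0	0.096138477
476.0	0.097419173
478.0	0.098583458
480.0	0.099601353
482.0	0.10045339
484.0	0.10112704
486.0	0.10161454
488.0	0.10191177
490.0	0.10201791
492.0	0.10193581
494.0	0.10167307
496.0	0.10124404
498.0	0.100673
500.0	0.099998621
502.0	0.099280107
504.0	0.098604739
506.0	0.098096445
508.0	0.097924238
510.0	0.09830862
512.0	0.09952324
514.0	0.10188855
516.0	0.10575416
518.0	0.11146743
520.0	0.11932783
522.0	0.12952969
524.0	0.14209944
526.0	0.15683738
528.0	0.17327641
530.0	0.19067019
532.0	0.20802084
534.0	0.22415016
536.0	0.23781043
538.0	0.24782237
540.0	0.25322065
542.0	0.25338462
544.0	0.24813334
546.0	0.23777109
548.0	0.223079
550.0	0.20525833
552.0	0.18583693
554.0	0.16655108
556.0	0.14920908
558.0	0.13553534
560.0	0.12698909
562.0	0.12455757
564.0	0.12854172
566.0	0.13837852
568.0	0.15256589
570.0	0.16875656
572.0	0.18405603
574.0	0.19549888
576.0	0.20060778
578.0	0.1978911
580.0	0.18713523
582.0	0.16940287
584.0	0.14674056
586.0	0.12169027
588.0	0.096753073
590.0	0.073950843
592.0	0.054579432
594.0	0.039172861
596.0	0.027633402
598.0	0.019448344
600.0	0.013914723
602.0	0.010317656
604.0	0.0080400867
606.0	0.0066081008
608.0	0.005690386
610.0	0.0050732662
612.0	0.0046283879
614.0	0.004283305
616.0	0.0039991673
618.0	0.0037558223
620.0	0.0035428327
622.0	0.0033545149
624.0	0.0031874064
626.0	0.0030390637
628.0	0.0029075279
630.0	0.0027911013
632.0	0.0026882568
634.0	0.0025976026
636.0	0.0025178656
638.0	0.0024478823
640.0	0.002386592
642.0	0.0023330305
644.0	0.0022863237
646.0	0.0022456816
648.0	0.0022103925
650.0	0.0021798167
652.0	0.0021533811
654.0	0.0021305737
656.0	0.0021109384
658.0	0.0020940698
660.0	0.0020796087
662.0	0.0020672377
664.0	0.0020566771
666.0	0.0020476809
668.0	0.0020400335
670.0	0.0020335463
672.0	0.0020280548
674.0	0.002023416
676.0	0.0020195056
678.0	0.0020162162
680.0	0.0020134549
682.0	0.0020111418
684.0	0.0020092081
686.0	0.002007595
688.0	0.0020062522
690.0	0.0020051366
692.0	0.0020042117
694.0	0.0020034465
696.0	0.0020028148
698.0	0.0020022944
700.0	0.0020018664
702.0	0.0020015153
704.0	0.0020012279
706.0	0.002000993
708.0	0.0020008014
710.0	0.0020006455
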