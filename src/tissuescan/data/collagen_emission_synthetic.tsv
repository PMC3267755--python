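# collagen emission synthetic
# SYNTHETIC parametric stand-in (Gaussian mixture), not measured data;
# replace via a user library directory to use measured spectra.
# columns: wavelength_nm	value (emission shape, unit area (nm^-1))
340.0	0.0022846997
342.0	0.0025637447
344.0	0.0028656554
346.0	0.0031906318
348.0	0.003538612
350.0	0.0039092438
352.0	0.0043018582
354.0	0.0047154481
356.0	0.0051486502
358.0	0.0055997332
360.0	0.0060665925
362.0	0.0065467513
364.0	0.0070373704
366.0	0.0075352646
368.0	0.0080369292
370.0	0.0085385734
372.0	0.0090361624
374.0	0.009525467
376.0	0.01000212
378.0	0.010461679
380.0	0.010899692
382.0	0.011311772
384.0	0.011693663
386.0	0.012041319
388.0	0.01235097
390.0	0.012619194
392.0	0.012842976
394.0	0.01301977
396.0	0.013147539
398.0	0.013224801
400.0	0.013250656
402.0	0.013224801
404.0	0.013147539
406.0	0.01301977
408.0	0.012842976
410.0	0.012619194
412.0	0.01235097
414.0	0.012041319
416.0	0.011693663
418.0	0.011311772
420.0	0.010899692
422.0	0.010461679
424.0	0.01000212
426.0	0.009525467
428.0	0.0090361624
430.0	0.0085385734
432.0	0.0080369292
434.0	0.0075352646
436.0	0.0070373704
438.0	0.0065467513
440.0	0.0060665925
442.0	0.0055997332
444.0	0.0051486502
446.0	0.0047154481
448.0	0.0043018582
450.0	0.0039092438
452.0	0.003538612
454.0	0.0031906318
456.0	0.0028656554
458.0	0.0025637447
460.0	0.0022846997
462.0	0.002028089
464.0	0.0017932813
466.0	0.0015794773
468.0	0.0013857404
470.0	0.0012110272
472.0	0.0010542157
474.0	0.00091413131
476.0	0.00078957107
478.0	0.00067932471
480.0	0.0005821932
482.0	0.00049700457
484.0	0.00042262694
486.0	0.00035797897
488.0	0.00030203785
490.0	0.0002538451
492.0	0.00021251017
494.0	0.00017721244
496.0	0.00014720149
498.0	0.00012179621
500.0	0.0001003827
502.0	8.2411437e-05
504.0	6.7393755e-05
506.0	5.4897852e-05
508.0	4.4544552e-05
510.0	3.6002891e-05
512.0	2.8985693e-05
514.0	2.3245213e-05
516.0	1.8568932e-05
518.0	1.4775557e-05
520.0	1.1711279e-05
522.0	9.246307e-06
524.0	7.2716982e-06
526.0	5.6964845e-06
528.0	4.4450999e-06
530.0	3.4550925e-06
532.0	2.6751083e-06
534.0	2.06313e-06
536.0	1.5849492e-06
538.0	1.2128515e-06
540.0	9.2449268e-07
542.0	7.0194462e-07
544.0	5.3089148e-07
546.0	3.9995599e-07
548.0	3.0013883e-07
550.0	2.2435497e-07
552.0	1.6705242e-07
554.0	1.2390058e-07
556.0	9.1537171e-08
558.0	6.7363579e-08
560.0	4.93806e-08
562.0	3.6057126e-08
564.0	2.6225839e-08
566.0	1.900077e-08
568.0	1.3712497e-08
570.0	9.8574696e-09
572.0	7.0585887e-09
574.0	5.0347028e-09
576.0	3.5771187e-09
578.0	2.5316076e-09
580.0	1.7846907e-09
582.0	1.2532366e-09
584.0	8.7661063e-10
586.0	6.1077875e-10
588.0	4.239012e-10
590.0	2.9305485e-10
592.0	2.0180723e-10
594.0	1.3842931e-10
596.0	9.4585143e-11
598.0	6.4375607e-11
600.0	4.3643873e-11
602.0	2.9473301e-11
604.0	1.9826123e-11
606.0	1.3284657e-11
608.0	8.8667907e-12
610.0	5.895031e-12
612.0	3.9039951e-12
614.0	2.5753483e-12
616.0	1.6922566e-12
618.0	1.1076435e-12
620.0	7.2216648e-13
622.0	4.6900577e-13
624.0	3.0340489e-13
626.0	1.9551069e-13
628.0	1.2549372e-13
630.0	8.0237426e-14
632.0	5.1101722e-14
634.0	3.2418851e-14
636.0	2.0486286e-14
638.0	1.2895328e-14
640.0	8.0854665e-15
642.0	5.0498829e-15
644.0	3.1416737e-15
646.0	1.9469033e-15
648.0	1.2017973e-15
650.0	7.3896115e-16
652.0	4.5260101e-16
654.0	2.7612961e-16
656.0	1.678085e-16
658.0	1.0158241e-16
660.0	6.1252886e-17
662.0	3.6790709e-17
664.0	2.2011685e-17
666.0	1.3118131e-17
668.0	7.7874306e-18
670.0	4.6048972e-18
672.0	2.7123718e-18
674.0	1.5914099e-18
676.0	9.3007595e-19
678.0	5.4144994e-19
680.0	3.1397983e-19
682.0	1.8136301e-19
684.0	1.0435163e-19
686.0	5.9807174e-20
688.0	3.4143722e-20
690.0	1.9416547e-20
692.0	1.0998581e-20
694.0	6.2059011e-21
696.0	3.4880008e-21
698.0	1.9527734e-21
700.0	1.089007e-21
702.0	6.0494098e-22
704.0	3.3473328e-22
706.0	1.8449658e-22
708.0	1.0129343e-22
710.0	5.5395918e-23
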